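import shutil
from pathlib import Path

import pytest

from hostclean.fastq import ReadRecord, write_fastq
from hostclean.refdb import ReferenceDb, build_index, write_fasta
from hostclean.simulate import synth_genome

HAVE_MINIMAP2 = shutil.which("minimap2") is not None

needs_minimap2 = pytest.mark.skipif(not HAVE_MINIMAP2, reason="minimap2 not on PATH")


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory) -> Path:
    return tmp_path_factory.mktemp("fixtures")


@pytest.fixture(scope="session")
def host_genome() -> dict:
    """1 Mb synthetic host genome (GC 0.41)."""
    return synth_genome(1_000_000, 0.41, seed=101, name="hostA")


@pytest.fixture(scope="session")
def microbe_genome() -> dict:
    """100 kb synthetic microbe genome, dissimilar to the host."""
    return synth_genome(100_000, 0.60, seed=202, name="micA")


@pytest.fixture(scope="session")
def host_fasta(fixture_dir, host_genome) -> Path:
    path = fixture_dir / "host.fa"
    write_fasta(host_genome, path)
    return path


@pytest.fixture(scope="session")
def microbe_fasta(fixture_dir, microbe_genome) -> Path:
    path = fixture_dir / "microbe.fa"
    write_fasta(microbe_genome, path)
    return path


@pytest.fixture(scope="session")
def host_db(host_fasta) -> ReferenceDb:
    return ReferenceDb(name="host-test", fasta_path=host_fasta)


@pytest.fixture(scope="session")
def short_index(host_db) -> Path:
    if not HAVE_MINIMAP2:
        pytest.skip("minimap2 not on PATH")
    return build_index(host_db, "short")


@pytest.fixture(scope="session")
def long_index(host_db) -> Path:
    if not HAVE_MINIMAP2:
        pytest.skip("minimap2 not on PATH")
    return build_index(host_db, "long")


def make_fastq(path: Path, records) -> Path:
    """Write (id, seq, qual) tuples or ReadRecords to a FASTQ path."""
    recs = [
        r if isinstance(r, ReadRecord) else ReadRecord(*r)
        for r in records
    ]
    write_fastq(recs, path)
    return path
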