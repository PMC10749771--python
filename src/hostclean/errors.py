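"""Exception hierarchy with stable process exit codes.

Exit codes: 2 usage, 3 environment, 4 format, 5 conservation, 6 pipeline.
"""


class HostcleanError(Exception):
    """Base class for all tool errors."""

    exit_code = 1


class UsageError(HostcleanError):
    """Invalid combination of arguments or inputs."""

    exit_code = 2


class ValidationError(UsageError):
    """Input data violates a documented precondition."""


class EnvError(HostcleanError):
    """Missing binary, missing index, or other environment problem."""

    exit_code = 3


class StaleIndexError(EnvError):
    """Index no longer matches the FASTA it was built from."""


class FormatError(HostcleanError):
    """Malformed FASTQ/SAM/TSV content."""

    exit_code = 4


class ConservationError(HostcleanError):
    """Read accounting failed: reads_in != reads_out + reads_removed."""

    exit_code = 5


class PipelineError(HostcleanError):
    """An external subprocess exited nonzero."""

    exit_code = 6
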