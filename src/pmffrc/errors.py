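"""Exception hierarchy with CLI exit codes.

Each error class carries the process exit code the command-line front end
returns when it propagates, so library users and shell users see the same
failure taxonomy: malformed input (2), backend failure (3), infeasible memory
budget (4), archive integrity / lossless-verification failure (5).
"""

from __future__ import annotations


class PmffrcError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class MalformedFastqError(PmffrcError):
    """FASTQ file violates the strict 4-line record structure."""

    exit_code = 2


class ConfigError(PmffrcError):
    """Bad backend specification or unusable configuration."""

    exit_code = 2


class BackendError(PmffrcError):
    """The cascaded compressor child process failed."""

    exit_code = 3

    def __init__(self, message: str, stderr: str = "") -> None:
        super().__init__(message)
        self.stderr = stderr


class BudgetError(PmffrcError):
    """The memory budget U_ram cannot accommodate the backend's resident memory."""

    exit_code = 4


class IntegrityError(PmffrcError):
    """Archive container is structurally corrupt."""

    exit_code = 5


class VerificationError(PmffrcError):
    """A recovered reads stream failed its fingerprint check."""

    exit_code = 5
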