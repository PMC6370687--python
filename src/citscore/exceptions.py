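"""Exception hierarchy for CIT scoring."""


class CITError(Exception):
    """Base class for all citscore errors."""


class SessionFormatError(CITError):
    """Malformed session file or inconsistent session structure."""


class InsufficientDataError(CITError):
    """Too few observations for the requested statistic."""


class DegenerateDataError(CITError):
    """Data admit no variability, so the statistic is undefined (s_p = 0)."""
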