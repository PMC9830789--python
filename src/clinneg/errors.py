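"""Exception hierarchy shared across the toolkit."""


class ClinnegError(Exception):
    """Base class for all toolkit errors."""


class ConfigurationError(ClinnegError):
    """A configuration object or argument is invalid."""


class ValidationError(ClinnegError):
    """Data violates a documented invariant.

    Carries an optional ``doc_id`` so callers can locate the offending record.
    """

    def __init__(self, message: str, doc_id: str | None = None):
        self.doc_id = doc_id
        if doc_id is not None:
            message = f"[doc_id={doc_id}] {message}"
        super().__init__(message)


class CorpusIOError(ClinnegError):
    """A corpus file could not be read or written."""


class AlignmentError(ClinnegError):
    """A subword/word alignment is missing or inconsistent."""
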