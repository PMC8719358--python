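"""Typed exceptions shared across the pipeline."""


class RetrotagError(Exception):
    """Base class for all package errors."""


class FormatError(RetrotagError):
    """A file violates its declared format (FASTA/MTX/TSV...)."""


class RegistryError(RetrotagError):
    """Invalid transgene registry (duplicate names, empty sequence...)."""


class QCError(RetrotagError):
    """QC filtering produced an unusable result (e.g. no cells retained)."""


class StageError(RetrotagError):
    """A pipeline stage aborted; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
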