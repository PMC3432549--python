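"""Exception hierarchy for the VLP detection pipeline."""


class VlpError(Exception):
    """Base class for all package errors."""


class RecordError(VlpError):
    """Malformed ECG record or I/O failure."""


class BeatDetectionError(VlpError):
    """No usable beats could be found in a record."""


class AlignmentError(VlpError):
    """Beat alignment failed (e.g. every beat rejected)."""


class FiducialError(VlpError):
    """A fiducial point (J point, QRSoff, onset) could not be located."""


class PipelineError(VlpError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
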