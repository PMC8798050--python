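"""Exception hierarchy.

``MotuinvError`` covers everything the package raises on bad user input;
the CLI maps it to exit code 1 and anything else to exit code 2.
"""


class MotuinvError(ValueError):
    """Invalid input or configuration supplied by the caller."""


class RaggedAlignmentError(MotuinvError):
    """Sequences in one alignment differ in length."""


class DuplicateIdError(MotuinvError):
    """The same terminal id occurs twice where ids must be unique."""
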