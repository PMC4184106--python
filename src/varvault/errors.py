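"""Exception hierarchy.

Every error the library raises deliberately derives from VarVaultError so
callers (and the CLI) can distinguish usage problems from genuine bugs.
"""


class VarVaultError(Exception):
    """Base class for all varvault errors."""


class InputError(VarVaultError):
    """A referenced input (file, sample, label) does not exist."""


class ParseError(VarVaultError):
    """A file's content is malformed; the message names the offending line."""


class ValidationError(VarVaultError):
    """A value violates a documented invariant or contract."""


class FormatError(VarVaultError):
    """A file lacks a required feature of its format (e.g. VCF without GT)."""


class UnsupportedInputError(VarVaultError):
    """The input is recognized but outside the supported subset."""


class StoreError(VarVaultError):
    """A warehouse-level problem: existing store, unknown sample, ref conflict."""
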