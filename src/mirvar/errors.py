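"""Exception hierarchy shared across the package."""


class MirvarError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(MirvarError, ValueError):
    """An argument violates an operation's precondition."""


class AlphabetError(InvalidInputError):
    """A sequence contains characters outside its declared alphabet."""


class DuplicateIdentifierError(InvalidInputError):
    """Two records share an identifier that must be unique."""


class ReferenceMismatchError(MirvarError):
    """The UTR base at a SNP position disagrees with the VCF REF allele."""

    def __init__(self, snp_id: str, pos: int, expected: str, found: str):
        self.snp_id = snp_id
        super().__init__(
            f"reference inconsistency for {snp_id}: UTR base at offset {pos} "
            f"is {found!r}, VCF REF is {expected!r}"
        )


class CapacityError(MirvarError):
    """The generator cannot place the requested number of non-overlapping sites."""


class DegenerateDesignError(InvalidInputError):
    """A model fit was requested on a degenerate design (e.g. constant predictor)."""


class UndefinedTestError(InvalidInputError):
    """A statistical test has no defined value (e.g. no non-zero paired differences)."""
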