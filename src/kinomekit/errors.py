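"""Exception hierarchy shared across the toolkit."""


class KinomekitError(Exception):
    """Base class for all kinomekit errors."""


class InvalidParameterError(KinomekitError, ValueError):
    """A numeric or structural parameter is out of its valid range."""


class GenerationError(KinomekitError):
    """A synthetic dataset could not be laid out as requested."""


class UnassignedIsoformError(KinomekitError):
    """Protein ids that match neither the isoform pattern nor the mapping."""

    def __init__(self, offenders):
        self.offenders = list(offenders)
        super().__init__(
            "protein ids could not be assigned to a gene: "
            + ", ".join(self.offenders[:10])
            + (" ..." if len(self.offenders) > 10 else "")
        )


class CatalogueError(KinomekitError):
    """A family is missing from the family->group catalogue."""


class IntegrityError(KinomekitError):
    """Duplicate identifiers or inconsistent cross-references in inputs."""


class AlignmentError(KinomekitError, ValueError):
    """A CDS pair is not a valid codon alignment."""


class InvalidSequenceError(KinomekitError, ValueError):
    """A sequence contains letters outside the expected alphabet."""
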