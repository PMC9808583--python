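"""Exception hierarchy for the cohortsim pipeline."""


class CohortsimError(Exception):
    """Base class for all cohortsim errors."""


class LexiconError(CohortsimError):
    """A lexicon file or entry is malformed or inconsistent with the scheme."""


class EmbeddingError(CohortsimError):
    """A term could not be mapped to a usable (non-zero, finite) vector."""


class PipelineOrderError(CohortsimError):
    """An operation was called on data that skipped a required earlier stage."""


class EmptyRepresentationError(CohortsimError):
    """A representation carries no labeled term within the configured universe."""


class IncomparableRepresentationsError(CohortsimError):
    """Two representations share no label on which a distance can be computed."""


class TransportError(CohortsimError):
    """The transportation solver failed to reach an optimal plan."""
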