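"""Exception hierarchy for the sepsis knowledge-graph toolkit."""


class SepsisKGError(Exception):
    """Base class for all toolkit errors."""


class ConfigurationError(SepsisKGError):
    """A config file or runtime configuration is invalid."""


class SchemaError(ConfigurationError):
    """The ontology violates a structural invariant (e.g. duplicate names)."""


class UnknownRelationError(SepsisKGError):
    """A relation label cannot be mapped to a canonical relation.

    Carries the raw label so callers can log or queue it.
    """

    def __init__(self, label: str):
        self.label = label
        super().__init__(f"unknown relation label: {label!r}")


class CorpusError(SepsisKGError):
    """A corpus file is malformed (bad record, duplicate document id)."""


class BackendError(SepsisKGError):
    """An extractor backend failed (transport, auth, timeout). Retriable."""


class GraphBuildError(SepsisKGError):
    """A triple could not be placed in the graph (unresolved argument)."""
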