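"""Exception types shared across the package."""


class WholeCellNetError(Exception):
    """Base class for all package-specific errors."""


class NetworkError(WholeCellNetError):
    """Structural violation of the bipartite reaction-graph model."""


class DuplicateIdError(NetworkError):
    """A node id was inserted twice into the shared namespace."""


class UnknownIdError(NetworkError):
    """An operation referenced a node id that is not in the network."""


class KBError(WholeCellNetError):
    """Schema or referential-integrity violation in a knowledge base."""


class ConfigError(WholeCellNetError):
    """An infeasible or inconsistent configuration."""


class TemplateError(WholeCellNetError):
    """A reaction template could not be instantiated for its substrate."""
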