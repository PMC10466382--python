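"""Exception hierarchy for the consite pipeline.

Each stage raises a distinct subclass so the CLI can map failures to
stable exit codes without string matching.
"""


class ConsiteError(Exception):
    """Base class for all consite errors."""


class PDBParseError(ConsiteError):
    """Malformed or empty PDB input."""


class ClusterFileError(ConsiteError):
    """Homolog cluster file problems (query token absent, unresolvable token)."""


class SuperpositionError(ConsiteError):
    """Superposition cannot proceed (too few atoms, degenerate geometry)."""


class SiteNotFoundError(ConsiteError):
    """The requested binding-site group does not exist in the query."""


class MissingInputError(ConsiteError):
    """A referenced input file does not exist."""
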