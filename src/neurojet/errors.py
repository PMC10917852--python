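"""Exception hierarchy for neurojet.

All errors derive from :class:`NeurojetError` so callers can catch the
package's failures with a single except clause; most also derive from a
matching builtin (ValueError / TypeError / RuntimeError).
"""


class NeurojetError(Exception):
    """Base class for all neurojet errors."""


class SWCParseError(NeurojetError, ValueError):
    """A malformed SWC row; the message names the 1-based line number."""


class SWCStructureError(NeurojetError, ValueError):
    """Node table violates tree invariants (ids, parents, root, cycles)."""


class RepeatNodeError(SWCStructureError):
    """Two connected nodes share (near-)identical positions.

    Traces with repeat nodes are rejected outright: a zero-length segment has
    no arc-length parameterization, so mapping is undefined on it.
    """


class JunctionConsistencyError(NeurojetError, ValueError):
    """Copies of a junction node were mapped to different positions."""


class BranchCorrespondenceError(NeurojetError, ValueError):
    """Two traces being compared do not decompose into matching branches."""


class DomainError(NeurojetError, ValueError):
    """A point fell outside the domain on which a diffeomorphism is defined."""


class CapabilityError(NeurojetError, TypeError):
    """An operation needs derivatives the diffeomorphism cannot provide."""


class DegenerateSegmentError(NeurojetError, ValueError):
    """A segment or probe grid is too short/degenerate to operate on."""


class DiffeoGenerationError(NeurojetError, RuntimeError):
    """The random-deformation generator could not produce an invertible map."""
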