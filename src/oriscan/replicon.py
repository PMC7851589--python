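"""Replicon geometry and the origin-centered, bidirectional coordinate transform.

Bacterial replication initiates at a single origin (*oriC*, or the *repC*
region on rhizobial secondary replicons) and proceeds bidirectionally: two
forks travel in opposite directions and meet at the terminus.  A position's
biologically meaningful coordinate is therefore not its raw index on the
GenBank sequence but its distance from the origin along its own replichore
(the arc replicated by the fork that copies it).  On a circular replicon the
origin and terminus split the molecule into a "right" replichore (increasing
raw coordinates away from the origin) and a "left" replichore (decreasing
raw coordinates, wrapping around position 1).  On a linear replicon the
origin sits inside the molecule and replication terminates at both ends;
positions left of the origin carry negative signed coordinates.

All public coordinates are 1-based inclusive (GenBank/GFF convention); the
origin itself maps to distance 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Optional, Tuple


class Topology(str, Enum):
    CIRCULAR = "circular"
    LINEAR = "linear"


class TerminusRule(str, Enum):
    EXPLICIT = "explicit"
    MIDPOINT = "midpoint"


class Replichore(str, Enum):
    RIGHT = "right"
    LEFT = "left"
    #: linear replicons: the arm right of the origin (positive signed coordinates)
    LONG_ARM = "long_arm"
    #: linear replicons: the arm left of the origin (negative signed coordinates)
    SHORT_ARM = "short_arm"


class RepliconConfigError(ValueError):
    """Inconsistent replicon geometry (unset terminus, midpoint on linear, ...)."""


class PositionDomainError(ValueError):
    """A raw position outside [1, length]."""


@dataclass(frozen=True)
class Replicon:
    """Geometry of one replication unit.

    For circular replicons ``terminus`` is a single 1-based position distinct
    from the origin.  For linear replicons replication terminates at both
    chromosome ends, so the termini are implicitly positions 1 and ``length``
    and ``terminus`` is ignored.
    """

    name: str
    length: int
    topology: Topology = Topology.CIRCULAR
    origin: int = 1
    terminus: Optional[int] = None
    terminus_rule: TerminusRule = TerminusRule.EXPLICIT

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise RepliconConfigError(f"replicon {self.name}: length must be positive")
        if not 1 <= self.origin <= self.length:
            raise RepliconConfigError(
                f"replicon {self.name}: origin {self.origin} outside [1, {self.length}]"
            )
        if self.topology is Topology.CIRCULAR and self.terminus is not None:
            if not 1 <= self.terminus <= self.length:
                raise RepliconConfigError(
                    f"replicon {self.name}: terminus {self.terminus} outside [1, {self.length}]"
                )
            if self.terminus == self.origin:
                raise RepliconConfigError(
                    f"replicon {self.name}: terminus coincides with origin"
                )

    @property
    def right_replichore_length(self) -> int:
        """Arc length from origin to terminus in the increasing direction."""
        if self.topology is Topology.LINEAR:
            return self.length - self.origin
        self._require_terminus()
        return (self.terminus - self.origin) % self.length

    @property
    def left_replichore_length(self) -> int:
        """Arc length from origin to terminus in the decreasing direction."""
        if self.topology is Topology.LINEAR:
            return self.origin - 1
        self._require_terminus()
        return (self.origin - self.terminus) % self.length

    def _require_terminus(self) -> None:
        if self.terminus is None:
            raise RepliconConfigError(
                f"replicon {self.name}: circular replicon needs a terminus; "
                "call assign_terminus() first"
            )


@dataclass(frozen=True)
class OrientedPosition:
    """A raw genomic position re-indexed relative to the origin.

    ``distance`` is the unsigned base-pair distance from the origin measured
    along the replichore containing the position.  ``signed`` is populated
    for linear replicons only: negative left of the origin (the arm given
    negative values in plots), positive to the right.
    """

    raw: int
    distance: int
    replichore: Replichore
    signed: Optional[int] = None


def transform_position(p: int, rep: Replicon) -> OrientedPosition:
    """Re-index raw position ``p`` as distance from the origin along its replichore.

    Circular: positions on the arc from the origin to the terminus in the
    increasing-coordinate direction belong to the right replichore with
    distance ``(p - origin) mod length``; all other positions belong to the
    left replichore with distance ``(origin - p) mod length``.  The terminus
    itself is reported on the right replichore (its left-replichore distance
    is ``length`` minus that; see :func:`terminus_distances`).

    Linear: ``signed = p - origin``; ``distance = |signed|``.
    """
    if not 1 <= p <= rep.length:
        raise PositionDomainError(
            f"position {p} outside [1, {rep.length}] on replicon {rep.name}"
        )
    if rep.topology is Topology.LINEAR:
        signed = p - rep.origin
        arm = Replichore.SHORT_ARM if signed < 0 else Replichore.LONG_ARM
        return OrientedPosition(raw=p, distance=abs(signed), replichore=arm, signed=signed)
    rep._require_terminus()
    d_right = (p - rep.origin) % rep.length
    if d_right <= rep.right_replichore_length:
        return OrientedPosition(raw=p, distance=d_right, replichore=Replichore.RIGHT)
    return OrientedPosition(
        raw=p, distance=(rep.origin - p) % rep.length, replichore=Replichore.LEFT
    )


def terminus_distances(rep: Replicon) -> Tuple[int, int]:
    """(right, left) replichore distances of the circular terminus.

    The two distances sum to the replicon length: the terminus is the one
    physical point reached by both forks.
    """
    if rep.topology is not Topology.CIRCULAR:
        raise RepliconConfigError("terminus_distances is defined for circular replicons")
    rep._require_terminus()
    return rep.right_replichore_length, rep.left_replichore_length


def assign_terminus(rep: Replicon, explicit: Optional[int] = None) -> Replicon:
    """Set the terminus explicitly (e.g. from a *dif*-site database) or by the midpoint rule.

    The midpoint rule places the terminus antipodal to the origin,
    ``((origin - 1 + floor(length/2)) mod length) + 1``, giving (near-)equal
    replichore lengths — the convention for replicons with no annotated
    *dif* site.
    """
    if explicit is not None:
        if rep.topology is Topology.LINEAR:
            raise RepliconConfigError(
                "linear replicons terminate at the chromosome ends; no terminus to assign"
            )
        return replace(rep, terminus=int(explicit), terminus_rule=TerminusRule.EXPLICIT)
    if rep.topology is Topology.LINEAR:
        raise RepliconConfigError("midpoint terminus rule applies to circular replicons only")
    ter = ((rep.origin - 1 + rep.length // 2) % rep.length) + 1
    return replace(rep, terminus=ter, terminus_rule=TerminusRule.MIDPOINT)


#: Largest origin shift exercised by the permutation test, in bp.
DEFAULT_MAX_SHIFT = 100_000


def shift_origin(rep: Replicon, delta: int, max_shift: int = DEFAULT_MAX_SHIFT) -> Replicon:
    """Return a copy with the origin moved by ``delta`` bp (permutation-test machinery).

    Circular origins wrap modularly; a midpoint-rule terminus is recomputed
    for the new origin, an explicit terminus is left where it is.  Linear
    shifts past either chromosome end are a domain error.
    """
    if abs(delta) > max_shift:
        raise PositionDomainError(
            f"origin shift {delta} exceeds the configured maximum {max_shift}"
        )
    new_origin_0 = (rep.origin - 1 + delta) % rep.length
    if rep.topology is Topology.LINEAR:
        unwrapped = rep.origin + delta
        if not 1 <= unwrapped <= rep.length:
            raise PositionDomainError(
                f"origin shift {delta} leaves linear replicon {rep.name}"
            )
        return replace(rep, origin=unwrapped)
    shifted = replace(rep, origin=new_origin_0 + 1)
    if rep.terminus_rule is TerminusRule.MIDPOINT:
        shifted = assign_terminus(shifted)
    return shifted


def transform_distances(positions, rep: Replicon):
    """Vectorized :func:`transform_position` over an integer array.

    Returns ``(distance, signed)`` arrays; ``signed`` is None for circular
    replicons.
    """
    import numpy as np

    p = np.asarray(positions, dtype=np.int64)
    if p.size and (p.min() < 1 or p.max() > rep.length):
        raise PositionDomainError(f"positions outside [1, {rep.length}] on {rep.name}")
    if rep.topology is Topology.LINEAR:
        signed = p - rep.origin
        return np.abs(signed), signed
    rep._require_terminus()
    d_right = (p - rep.origin) % rep.length
    d_left = (rep.origin - p) % rep.length
    distance = np.where(d_right <= rep.right_replichore_length, d_right, d_left)
    return distance, None


def replicon_from_config(cfg: dict) -> Replicon:
    """Build a Replicon from a config mapping.

    Expected keys: ``name``, ``length``, ``topology`` (circular|linear),
    ``origin``, and for circular replicons ``terminus`` (an integer or the
    string ``"midpoint"``).
    """
    topology = Topology(cfg.get("topology", "circular"))
    rep = Replicon(
        name=str(cfg["name"]),
        length=int(cfg["length"]),
        topology=topology,
        origin=int(cfg.get("origin", 1)),
    )
    if topology is Topology.CIRCULAR:
        ter = cfg.get("terminus", "midpoint")
        if isinstance(ter, str) and ter.lower() == "midpoint":
            rep = assign_terminus(rep)
        else:
            rep = assign_terminus(rep, explicit=int(ter))
    return rep
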