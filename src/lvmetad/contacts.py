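"""Contact counting through the rational switching function.

The H-bond/salt-bridge observable N is a sum of smooth pairwise
occupancies

    s(r) = (1 − x^n) / (1 − x^m),   x = (r − d0)/r0,  m > n > 0,

which decays from 1 at contact to 0 at large separation.  The defaults
n = 8, m = 12, d0 = 0, r0 = 2.5 Å match common practice for
hydrogen-bond counting in biased simulations.  The same per-pair
occupancies double as a "fingerprint" of a pose, which a leader-style
clustering turns into discrete pose labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, SelectionError

__all__ = [
    "SwitchingParams",
    "ContactSet",
    "PoseClustering",
    "switch",
    "hbond_count",
    "fingerprint",
    "cluster_poses",
]

_LIMIT_TOL = 1e-10  # |1 - x^m| below this: use the n/m L'Hôpital limit


@dataclass(frozen=True)
class SwitchingParams:
    """Exponents and lengths of the rational switching function."""

    n: int = 8
    m: int = 12
    d0: float = 0.0
    r0: float = 2.5

    def __post_init__(self):
        if not (self.m > self.n > 0):
            raise ParameterError(f"need m > n > 0, got n={self.n}, m={self.m}")
        if self.r0 <= 0:
            raise ParameterError("r0 must be > 0")
        if self.d0 < 0:
            raise ParameterError("d0 must be >= 0")


@dataclass(frozen=True)
class ContactSet:
    """Donor-acceptor pair list (by site id) plus switching parameters."""

    pairs: tuple[tuple[str, str], ...]
    params: SwitchingParams = SwitchingParams()

    def __post_init__(self):
        pairs = tuple((str(a), str(b)) for a, b in self.pairs)
        if len(set(pairs)) != len(pairs):
            raise ParameterError("duplicate pairs in ContactSet")
        object.__setattr__(self, "pairs", pairs)


def switch(r, p: SwitchingParams = SwitchingParams()):
    """Occupancy s(r) ∈ [0, 1]; scalar in → float out, array in → array out.

    x < 0 (r below d0) is clamped to s = 1 (fully formed contact); the
    removable 0/0 singularity at x = 1 is evaluated as the analytic
    limit n/m.
    """
    scalar = np.ndim(r) == 0
    r = np.atleast_1d(np.asarray(r, dtype=float))
    if np.any(r < 0):
        raise ParameterError("distances must be >= 0")
    x = np.maximum((r - p.d0) / p.r0, 0.0)
    xn = x**p.n
    xm = x**p.m
    denom = 1.0 - xm
    near_one = np.abs(denom) < _LIMIT_TOL
    safe = np.where(near_one, 1.0, denom)
    s = np.where(near_one, p.n / p.m, (1.0 - xn) / safe)
    return float(s[0]) if scalar else s


def _pair_distances(frame, contacts: ContactSet) -> np.ndarray:
    d = np.empty(len(contacts.pairs))
    for i, (a, b) in enumerate(contacts.pairs):
        try:
            pa, pb = frame[a], frame[b]
        except KeyError as exc:
            raise SelectionError(f"pair ({a}, {b}): site {exc.args[0]!r} missing from frame") from None
        d[i] = np.linalg.norm(np.asarray(pa, dtype=float) - np.asarray(pb, dtype=float))
    return d


def hbond_count(frame, contacts: ContactSet) -> float:
    """N = Σ_pairs s(r_ij) for one frame (a mapping site id → position)."""
    return float(np.sum(switch(_pair_distances(frame, contacts), contacts.params)))


def fingerprint(frame, contacts: ContactSet) -> np.ndarray:
    """Per-pair occupancy vector (the pose fingerprint); sums to N."""
    return np.atleast_1d(switch(_pair_distances(frame, contacts), contacts.params))


@dataclass(frozen=True)
class PoseClustering:
    """Labels (per frame), cluster populations and medoid frame indices."""

    labels: np.ndarray
    populations: np.ndarray
    medoids: np.ndarray

    @property
    def n_clusters(self) -> int:
        return len(self.populations)


def cluster_poses(frames, contacts: ContactSet, cutoff: float) -> PoseClustering:
    """Leader clustering of pose fingerprints.

    Frames are visited in order; a frame joins the first existing
    cluster whose leader fingerprint lies within Euclidean distance
    ``cutoff``, otherwise it founds a new cluster (and becomes its
    leader).  Deterministic given frame order.  Medoids minimize the
    within-cluster sum of pairwise fingerprint distances.
    """
    frames = list(frames)
    if not frames:
        raise ParameterError("need at least one frame")
    if cutoff <= 0:
        raise ParameterError("cutoff must be > 0")
    fps = np.stack([fingerprint(f, contacts) for f in frames])
    leaders: list[np.ndarray] = []
    labels = np.empty(len(fps), dtype=int)
    for i, fp in enumerate(fps):
        for j, lead in enumerate(leaders):
            if np.linalg.norm(fp - lead) <= cutoff:
                labels[i] = j
                break
        else:
            labels[i] = len(leaders)
            leaders.append(fp)
    populations = np.bincount(labels, minlength=len(leaders))
    medoids = np.empty(len(leaders), dtype=int)
    for j in range(len(leaders)):
        members = np.nonzero(labels == j)[0]
        sub = fps[members]
        dist = np.linalg.norm(sub[:, None, :] - sub[None, :, :], axis=-1)
        medoids[j] = members[int(np.argmin(dist.sum(axis=1)))]
    return PoseClustering(labels=labels, populations=populations, medoids=medoids)
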