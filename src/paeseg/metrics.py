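"""Scoring predicted segmentations against reference delineations.

Two complementary scores are used in the domain-segmentation literature:

* **IoU** — matched predicted and reference domains are compared as residue
  sets by intersection-over-union; the per-pair scores of the best
  one-to-one matching are summed and divided by ``max(n_pred, n_ref)``, so
  over- and under-segmentation are penalized symmetrically.  1 means a
  perfect overlap of every domain.
* **DBD** (domain boundary distance) — each boundary earns
  ``max(0, 1 - d/8)`` where ``d`` is its residue distance to the nearest
  boundary of the other segmentation: a full point for an exact hit, minus
  1/8 per residue of displacement.  The score averages the accuracy
  component (predicted vs reference) and the sensitivity component
  (reference vs predicted).

Boundaries are the half-integer edges of domain regions (``start - 1/2``,
``end + 1/2``), protein termini excluded.  Edges shared with linkers or
disordered regions are counted; a reference without disorder annotations
simply has fewer boundaries.

Accuracy/sensitivity permissibility curves report the fraction of
boundaries that land within 0..7 residues of a counterpart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .segment import Segmentation

__all__ = [
    "EvalReport",
    "AggregateReport",
    "domain_boundaries",
    "iou_score",
    "dbd_score",
    "boundary_curves",
    "evaluate",
    "aggregate",
]

DBD_PENALTY_PER_RESIDUE = 1.0 / 8.0
DEFAULT_MAX_DIST = 7


@dataclass(frozen=True)
class EvalReport:
    """Per-protein evaluation of a predicted vs reference segmentation."""

    protein_id: str
    iou: float
    dbd: float
    accuracy_at: dict[int, float]
    sensitivity_at: dict[int, float]
    n_pred_domains: int
    n_ref_domains: int


@dataclass(frozen=True)
class AggregateReport:
    """Mean +/- population SD of IoU and DBD plus averaged curves."""

    n_proteins: int
    iou_mean: float
    iou_sd: float
    dbd_mean: float
    dbd_sd: float
    accuracy_at: dict[int, float]
    sensitivity_at: dict[int, float]


def _check_lengths(pred: Segmentation, ref: Segmentation) -> None:
    if pred.length != ref.length:
        raise ValueError(
            f"length mismatch: predicted {pred.length} vs reference {ref.length}"
        )


def domain_boundaries(seg: Segmentation) -> tuple[float, ...]:
    """Half-integer internal edges of the segmentation's domains.

    For a domain ``start..end`` the edges are ``start - 0.5`` and
    ``end + 0.5``; the chain termini (``0.5`` and ``L + 0.5``) are excluded,
    and edges shared by two abutting domains are counted once.
    """
    edges: set[float] = set()
    for reg in seg.domains:
        if reg.start > 1:
            edges.add(reg.start - 0.5)
        if reg.end < seg.length:
            edges.add(reg.end + 0.5)
    return tuple(sorted(edges))


def _domain_residue_sets(seg: Segmentation) -> list[frozenset[int]]:
    return [frozenset(range(r.start, r.end + 1)) for r in seg.domains]


def iou_score(pred: Segmentation, ref: Segmentation) -> float:
    """Best-matching intersection-over-union of domain residue sets.

    Linker and disordered residues are excluded.  A one-to-one matching
    between predicted and reference domains maximizing the summed IoU is
    found by exact assignment; the sum is normalized by
    ``max(n_pred, n_ref)`` so unmatched domains contribute zero.
    """
    _check_lengths(pred, ref)
    P = _domain_residue_sets(pred)
    R = _domain_residue_sets(ref)
    if not P and not R:
        return 1.0
    if not P or not R:
        return 0.0
    iou = np.zeros((len(P), len(R)))
    for i, p in enumerate(P):
        for j, r in enumerate(R):
            inter = len(p & r)
            if inter:
                iou[i, j] = inter / len(p | r)
    rows, cols = linear_sum_assignment(-iou)
    return float(iou[rows, cols].sum() / max(len(P), len(R)))


def _min_distances(from_b: tuple[float, ...], to_b: tuple[float, ...]) -> np.ndarray:
    """Residue distance of each boundary in ``from_b`` to the nearest in ``to_b``."""
    a = np.asarray(from_b, dtype=float)[:, None]
    b = np.asarray(to_b, dtype=float)[None, :]
    return np.abs(a - b).min(axis=1)


def dbd_score(pred: Segmentation, ref: Segmentation) -> float:
    """Domain boundary distance score in [0, 1].

    Per-boundary score ``max(0, 1 - d/8)``; the accuracy component averages
    predicted boundaries against the reference set and the sensitivity
    component the reverse; the DBD is their mean.  Conventions: both
    boundary sets empty -> 1; exactly one empty -> 0.
    """
    _check_lengths(pred, ref)
    pb = domain_boundaries(pred)
    rb = domain_boundaries(ref)
    if not pb and not rb:
        return 1.0
    if not pb or not rb:
        return 0.0
    acc = np.maximum(0.0, 1.0 - _min_distances(pb, rb) * DBD_PENALTY_PER_RESIDUE).mean()
    sens = np.maximum(0.0, 1.0 - _min_distances(rb, pb) * DBD_PENALTY_PER_RESIDUE).mean()
    return float((acc + sens) / 2.0)


def boundary_curves(pred: Segmentation, ref: Segmentation,
                    max_dist: int = DEFAULT_MAX_DIST) -> tuple[dict[int, float], dict[int, float]]:
    """Accuracy and sensitivity over a permissibility range 0..``max_dist``.

    ``accuracy_at[X]`` is the fraction of predicted boundaries lying within
    X residues of some reference boundary; ``sensitivity_at[X]`` the
    fraction of reference boundaries within X of some predicted one.  Both
    curves are non-decreasing in X.  When one side has no boundaries its
    curve is constant 1.0 if the other side is also empty, else 0.0.
    """
    _check_lengths(pred, ref)
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")
    pb = domain_boundaries(pred)
    rb = domain_boundaries(ref)
    dists = range(max_dist + 1)

    def curve(from_b: tuple[float, ...], to_b: tuple[float, ...]) -> dict[int, float]:
        if not from_b:
            return {x: (1.0 if not to_b else 0.0) for x in dists}
        if not to_b:
            return {x: 0.0 for x in dists}
        d = _min_distances(from_b, to_b)
        return {x: float((d <= x).mean()) for x in dists}

    return curve(pb, rb), curve(rb, pb)


def evaluate(pred: Segmentation, ref: Segmentation,
             max_dist: int = DEFAULT_MAX_DIST) -> EvalReport:
    """Full per-protein report: IoU, DBD and both permissibility curves."""
    acc, sens = boundary_curves(pred, ref, max_dist)
    return EvalReport(
        protein_id=pred.protein_id,
        iou=iou_score(pred, ref),
        dbd=dbd_score(pred, ref),
        accuracy_at=acc,
        sensitivity_at=sens,
        n_pred_domains=pred.n_domains,
        n_ref_domains=ref.n_domains,
    )


def aggregate(reports: list[EvalReport]) -> AggregateReport:
    """Mean and population standard deviation over proteins; curves averaged per distance."""
    if not reports:
        raise ValueError("no reports to aggregate")
    ious = np.array([r.iou for r in reports])
    dbds = np.array([r.dbd for r in reports])
    dists = sorted(reports[0].accuracy_at)
    acc = {x: float(np.mean([r.accuracy_at[x] for r in reports])) for x in dists}
    sens = {x: float(np.mean([r.sensitivity_at[x] for r in reports])) for x in dists}
    return AggregateReport(
        n_proteins=len(reports),
        iou_mean=float(ious.mean()),
        iou_sd=float(ious.std(ddof=0)),
        dbd_mean=float(dbds.mean()),
        dbd_sd=float(dbds.std(ddof=0)),
        accuracy_at=acc,
        sensitivity_at=sens,
    )
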