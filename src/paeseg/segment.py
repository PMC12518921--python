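"""Domain segmentation of a protein chain from its PAE matrix.

The algorithm partitions a chain into domains, inter-domain linkers and
terminal disordered regions using only the predicted aligned error matrix,
in five steps:

1. *Cluster.* Each residue is represented by its row of the symmetrized PAE
   matrix (its error profile against every other residue).  Rows are grouped
   by agglomerative single-linkage clustering on Euclidean distances, cut at
   the smallest height that yields at most ``max_cluster_fraction * L`` flat
   clusters.  Compact domains produce long clusters; linkers and frayed ends
   shatter into many small, often singleton, clusters.
2. *Identify domains.* Clusters larger than ``min_domain_cluster`` residues
   become preliminary domains; everything else is tagged non-domain.
3. *Correct ends.* A terminal non-domain run shorter than
   ``terminal_merge_len`` is absorbed into the nearest domain.  Longer runs
   are tested for disorder: a residue is poorly connected when it has at
   most ``disorder_neighbor_max`` low-PAE (< ``low_pae``) contacts inside
   the run; if more than ``disorder_fraction`` of the run is poorly
   connected the run is a disordered terminus, otherwise it is a loosely
   packed but ordered extension of the adjacent domain and is merged.
4. *Correct artifacts.* Residues mislabelled inside a domain's span are
   repaired so every domain is one contiguous stretch.
5. *Adjust linkers.* Boundary residues of a candidate linker are handed to
   the flanking domain while they keep low PAE with at least
   ``linker_support`` residues of the whole chain; what survives is the
   linker (possibly empty — domains may abut).

The result is an ordered tiling of residues 1..L into domain / linker /
disordered regions.  Coordinates are 1-based and inclusive throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .pae_io import PaeMatrix, symmetrize

__all__ = [
    "SegmentationParams",
    "ResidueLabels",
    "Region",
    "Segmentation",
    "NON_DOMAIN",
    "LINKER",
    "DISORDERED",
    "cluster_residues",
    "assign_domains",
    "is_disordered",
    "correct_ends",
    "correct_artifacts",
    "adjust_linkers",
    "segment_pae",
]

logger = logging.getLogger(__name__)

# Residue label codes: positive integers are cluster / domain indices.
NON_DOMAIN = 0
LINKER = -1
DISORDERED = -2


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable thresholds of the segmentation algorithm.

    Attributes
    ----------
    max_cluster_fraction
        Maximum number of flat clusters as a fraction of chain length L
        (``maxclust = max(2, round(fraction * L))``).  Deliberately much
        larger than the expected number of domains so that loose regions
        shatter into small clusters.
    min_domain_cluster
        A cluster is a preliminary domain only if it holds strictly more
        than this many residues.
    terminal_merge_len
        Terminal non-domain runs strictly shorter than this merge into the
        nearest domain without a disorder test.
    low_pae
        PAE below this (angstroms) counts as a "low" contact.
    disorder_neighbor_max
        A residue is poorly connected when it has at most this many low-PAE
        neighbours within the region under test.
    disorder_fraction
        A region is disordered when strictly more than this fraction of its
        residues are poorly connected.
    linker_support
        A boundary residue joins the adjacent domain while it has low PAE
        with at least this many residues of the whole chain.
    """

    max_cluster_fraction: float = 0.10
    min_domain_cluster: int = 25
    terminal_merge_len: int = 20
    low_pae: float = 5.0
    disorder_neighbor_max: int = 5
    disorder_fraction: float = 0.80
    linker_support: int = 25

    def __post_init__(self) -> None:
        if not 0.0 < self.max_cluster_fraction <= 1.0:
            raise ValueError("max_cluster_fraction must be in (0, 1]")
        for name in ("min_domain_cluster", "terminal_merge_len",
                     "disorder_neighbor_max", "linker_support"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 < self.disorder_fraction < 1.0:
            raise ValueError("disorder_fraction must be in (0, 1)")
        if self.low_pae <= 0:
            raise ValueError("low_pae must be positive")


@dataclass
class ResidueLabels:
    """Per-residue tags at some stage of the pipeline.

    ``codes`` holds one integer per residue: positive values are cluster
    indices (``stage == "cluster"``) or domain indices (``stage ==
    "domain"``); :data:`NON_DOMAIN`, :data:`LINKER` and :data:`DISORDERED`
    tag the remaining residues.
    """

    codes: np.ndarray
    stage: str  # "cluster" or "domain"

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.codes.ndim != 1 or self.codes.size == 0:
            raise ValueError("codes must be a non-empty 1-D array")
        if self.stage not in ("cluster", "domain"):
            raise ValueError(f"unknown stage {self.stage!r}")

    @property
    def length(self) -> int:
        return self.codes.size


@dataclass(frozen=True)
class Region:
    """One segment: 1-based inclusive interval with a category."""

    start: int
    end: int
    kind: str  # "domain" | "linker" | "disordered"

    def __post_init__(self) -> None:
        if self.kind not in ("domain", "linker", "disordered"):
            raise ValueError(f"unknown region kind {self.kind!r}")
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad interval {self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Segmentation:
    """An ordered, non-overlapping tiling of residues 1..L.

    Domains are implicitly numbered 1..n from the N- to the C-terminus by
    their order in ``regions``.  Two adjacent regions may both be domains
    (zero-length linker); a disordered region always touches a terminus.
    """

    protein_id: str
    length: int
    regions: tuple[Region, ...]

    def __post_init__(self) -> None:
        if not self.regions:
            raise ValueError("segmentation has no regions")
        pos = 1
        for reg in self.regions:
            if reg.start != pos:
                raise ValueError(f"regions do not tile 1..{self.length} (gap/overlap at {pos})")
            pos = reg.end + 1
        if pos != self.length + 1:
            raise ValueError(f"regions do not cover 1..{self.length}")
        for a, b in zip(self.regions, self.regions[1:]):
            if a.kind == "linker" and b.kind == "linker":
                raise ValueError("two adjacent linker regions")
        for reg in self.regions:
            if reg.kind == "disordered" and reg.start != 1 and reg.end != self.length:
                raise ValueError("disordered region does not touch a terminus")

    @property
    def domains(self) -> tuple[Region, ...]:
        return tuple(r for r in self.regions if r.kind == "domain")

    @property
    def n_domains(self) -> int:
        return len(self.domains)


def _runs(codes: np.ndarray) -> Iterator[tuple[int, int, int]]:
    """Yield maximal runs of equal code as (start_idx, end_idx, code), 0-based inclusive."""
    start = 0
    for i in range(1, codes.size + 1):
        if i == codes.size or codes[i] != codes[start]:
            yield start, i - 1, int(codes[start])
            start = i


def cluster_residues(sym: PaeMatrix, params: SegmentationParams | None = None) -> ResidueLabels:
    """Step 1: single-linkage clustering of PAE row profiles.

    Each residue is the row vector of the symmetrized matrix; pairwise
    distances are Euclidean; the dendrogram is cut at the smallest height
    yielding at most ``maxclust = max(2, round(max_cluster_fraction * L))``
    flat clusters.  Cluster indices are renumbered 1..k in order of first
    appearance along the chain.
    """
    params = params or SegmentationParams()
    if not sym.symmetrized:
        raise ValueError("cluster_residues requires a symmetrized matrix")
    L = sym.length
    if L < 2:
        raise ValueError("protein too short")
    maxclust = max(2, round(params.max_cluster_fraction * L))
    tree = linkage(pdist(sym.values, metric="euclidean"), method="single")
    flat = fcluster(tree, t=maxclust, criterion="maxclust")
    # stable renumbering by first occurrence
    codes = np.zeros(L, dtype=np.int64)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(flat):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        codes[i] = mapping[lab]
    return ResidueLabels(codes=codes, stage="cluster")


def assign_domains(labels: ResidueLabels, params: SegmentationParams | None = None) -> ResidueLabels:
    """Step 2: clusters above the size threshold become domains.

    Clusters with strictly more than ``min_domain_cluster`` residues are
    domains, numbered 1..n by position of their first residue; all other
    residues are tagged non-domain.
    """
    params = params or SegmentationParams()
    if labels.stage != "cluster":
        raise ValueError("assign_domains expects cluster-stage labels")
    codes = labels.codes
    sizes = np.bincount(codes)
    domain_clusters = [k for k in range(1, sizes.size) if sizes[k] > params.min_domain_cluster]
    # order by first residue
    domain_clusters.sort(key=lambda k: int(np.argmax(codes == k)))
    out = np.full_like(codes, NON_DOMAIN)
    for d, k in enumerate(domain_clusters, start=1):
        out[codes == k] = d
    return ResidueLabels(codes=out, stage="domain")


def is_disordered(region: tuple[int, int], sym: PaeMatrix,
                  params: SegmentationParams | None = None) -> bool:
    """Disorder test for a contiguous interval (1-based, inclusive).

    Counts, for each residue, its low-PAE neighbours *within the region*
    (self and diagonal excluded).  The region is disordered when strictly
    more than ``disorder_fraction`` of its residues have at most
    ``disorder_neighbor_max`` such neighbours — i.e. when nearly every
    residue is close only to its sequence neighbours.
    """
    params = params or SegmentationParams()
    start, end = region
    if end < start:
        raise ValueError("empty region")
    if not (1 <= start and end <= sym.length):
        raise ValueError(f"region {start}-{end} outside 1..{sym.length}")
    block = sym.values[start - 1:end, start - 1:end]
    low = block < params.low_pae
    np.fill_diagonal(low, False)
    neighbor_counts = low.sum(axis=1)
    n = end - start + 1
    poorly_connected = int((neighbor_counts <= params.disorder_neighbor_max).sum())
    return poorly_connected / n > params.disorder_fraction


def correct_ends(labels: ResidueLabels, sym: PaeMatrix,
                 params: SegmentationParams | None = None) -> ResidueLabels:
    """Step 3: resolve terminal non-domain runs (N-terminus first, then C).

    A run shorter than ``terminal_merge_len`` merges into the adjacent
    domain.  A longer run is kept as a disordered terminus if
    :func:`is_disordered` says so, otherwise it too merges (a loosely
    packed but ordered extension of the domain).
    """
    params = params or SegmentationParams()
    codes = labels.codes.copy()
    if not (codes > 0).any():
        raise ValueError("correct_ends requires at least one domain")
    L = codes.size

    # N-terminal run
    n_end = 0
    while n_end < L and codes[n_end] == NON_DOMAIN:
        n_end += 1
    if 0 < n_end:
        run_len = n_end
        if run_len < params.terminal_merge_len:
            codes[:n_end] = codes[n_end]
        elif is_disordered((1, n_end), sym, params):
            codes[:n_end] = DISORDERED
        else:
            codes[:n_end] = codes[n_end]

    # C-terminal run
    c_start = L
    while c_start > 0 and codes[c_start - 1] == NON_DOMAIN:
        c_start -= 1
    if c_start < L:
        run_len = L - c_start
        if run_len < params.terminal_merge_len:
            codes[c_start:] = codes[c_start - 1]
        elif is_disordered((c_start + 1, L), sym, params):
            codes[c_start:] = DISORDERED
        else:
            codes[c_start:] = codes[c_start - 1]

    return ResidueLabels(codes=codes, stage="domain")


def _renumber_domains(codes: np.ndarray) -> np.ndarray:
    """Renumber domain codes 1..n in order of first residue."""
    out = codes.copy()
    mapping: dict[int, int] = {}
    for i in range(codes.size):
        c = int(codes[i])
        if c > 0 and c not in mapping:
            mapping[c] = len(mapping) + 1
    for old, new in mapping.items():
        out[codes == old] = new
    return out


def correct_artifacts(labels: ResidueLabels) -> ResidueLabels:
    """Step 4: repair clustering artifacts so every domain is contiguous.

    Scanning from the N-terminus: (1) any stretch lying strictly between
    two runs of the same domain — whether non-domain residues or residues
    of another domain — is relabelled to that domain; (2) should a domain
    still be split after that, only its longest run survives (ties go to
    the N-terminal-most run) and the rest become non-domain.  Domains are
    renumbered 1..n by position afterwards.
    """
    codes = labels.codes.copy()
    # rule (1): absorb everything between the first and last residue of
    # each domain, processing domains in N->C order.  A domain enclosed in
    # another's gap is absorbed entirely and vanishes.
    order = [c for _, _, c in _runs(codes) if c > 0]
    seen: set[int] = set()
    for d in order:
        if d in seen:
            continue
        seen.add(d)
        idx = np.flatnonzero(codes == d)
        if idx.size == 0:
            continue  # already absorbed by an earlier domain
        codes[idx[0]:idx[-1] + 1] = d

    # rule (2): safety net — if interleaving left a domain split by another
    # domain, keep its longest run (N-terminal-most on ties).
    changed = True
    while changed:
        changed = False
        runs_by_domain: dict[int, list[tuple[int, int]]] = {}
        for s, e, c in _runs(codes):
            if c > 0:
                runs_by_domain.setdefault(c, []).append((s, e))
        for d, rr in runs_by_domain.items():
            if len(rr) > 1:
                keep = max(rr, key=lambda se: (se[1] - se[0], -se[0]))
                for s, e in rr:
                    if (s, e) != keep:
                        codes[s:e + 1] = NON_DOMAIN
                changed = True
                break

    return ResidueLabels(codes=_renumber_domains(codes), stage="domain")


def _global_support(sym: PaeMatrix, params: SegmentationParams) -> np.ndarray:
    """Per-residue count of low-PAE contacts over the whole chain (self excluded)."""
    low = sym.values < params.low_pae
    np.fill_diagonal(low, False)
    return low.sum(axis=1)


def adjust_linkers(labels: ResidueLabels, sym: PaeMatrix,
                   params: SegmentationParams | None = None) -> ResidueLabels:
    """Step 5: pull well-connected linker-edge residues into their domain.

    For each interior non-domain run between domains *a* (left) and *b*
    (right): walk inward from the left edge assigning residues to *a* while
    their whole-chain low-PAE contact count is at least ``linker_support``;
    stop at the first failure; then walk inward from the right edge toward
    *b* the same way (the walks never cross; the left walk has priority).
    Whatever survives is the linker; a run may vanish entirely, leaving the
    two domains adjacent.
    """
    params = params or SegmentationParams()
    codes = labels.codes.copy()
    support = _global_support(sym, params)
    L = codes.size

    for s, e, c in list(_runs(codes)):
        if c != NON_DOMAIN:
            continue
        left = codes[s - 1] if s > 0 else None
        right = codes[e + 1] if e + 1 < L else None
        if left is None or right is None or left <= 0 or right <= 0:
            # A terminal non-domain run at this stage is unexpected (step 3
            # resolves termini); absorb it into the adjacent domain.
            logger.warning("stray terminal non-domain run %d-%d merged", s + 1, e + 1)
            codes[s:e + 1] = left if left is not None and left > 0 else right
            continue
        i, j = s, e
        while i <= j and support[i] >= params.linker_support:
            codes[i] = left
            i += 1
        while j >= i and support[j] >= params.linker_support:
            codes[j] = right
            j -= 1
        if i <= j:
            codes[i:j + 1] = LINKER

    return ResidueLabels(codes=codes, stage="domain")


def _labels_to_segmentation(labels: ResidueLabels, protein_id: str) -> Segmentation:
    kinds = {LINKER: "linker", DISORDERED: "disordered"}
    regions = []
    for s, e, c in _runs(labels.codes):
        kind = "domain" if c > 0 else kinds.get(c)
        if kind is None:
            raise ValueError(f"unresolved non-domain residues at {s + 1}-{e + 1}")
        regions.append(Region(start=s + 1, end=e + 1, kind=kind))
    return Segmentation(protein_id=protein_id, length=labels.length, regions=tuple(regions))


def segment_pae(pae: PaeMatrix, params: SegmentationParams | None = None,
                protein_id: str | None = None) -> Segmentation:
    """Run the full five-step segmentation on a PAE matrix.

    The input may be raw or already symmetrized; symmetrization is applied
    internally.  Deterministic: identical input and parameters always give
    the identical segmentation.

    Degenerate inputs where step 2 finds no domain at all yield a single
    region covering the whole chain — of kind ``domain`` when
    ``L > min_domain_cluster`` (one compact chain the clustering could not
    subdivide) and ``disordered`` otherwise.
    """
    params = params or SegmentationParams()
    pid = protein_id or pae.protein_id
    sym = pae if pae.symmetrized else symmetrize(pae)
    labels = cluster_residues(sym, params)
    labels = assign_domains(labels, params)
    if not (labels.codes > 0).any():
        kind = "domain" if labels.length > params.min_domain_cluster else "disordered"
        return Segmentation(protein_id=pid, length=labels.length,
                            regions=(Region(1, labels.length, kind),))
    labels = correct_ends(labels, sym, params)
    labels = correct_artifacts(labels)
    labels = adjust_linkers(labels, sym, params)
    seg = _labels_to_segmentation(labels, pid)
    for reg in seg.domains:
        if len(reg) <= params.min_domain_cluster:
            logger.info("%s: domain %d-%d smaller than %d residues after repair",
                        pid, reg.start, reg.end, params.min_domain_cluster)
    return seg
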