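"""Somatic point-mutation hotspot detection.

The genome is tiled into fixed-width non-overlapping windows (default 21 bp)
and, per window, the number of distinct samples carrying at least one somatic
point mutation inside it is counted.  Under the null, sample *i* with ``m_i``
total mutations placed uniformly over a usable genome of length ``G`` hits a
fixed ``w``-bp window with probability ``p_i = 1 - (1 - w/G)**m_i``; the
window count K is then Poisson-binomial distributed, and a window with count
``k`` is scored by the exact tail P(K >= k).  Windows overlapping mappability-
masked or repeat intervals, or lying on excluded chromosomes (chrY by
default), are flagged and never reported as hotspots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .core import ChromSizes, GenomicInterval, MutationRecord, chrom_sort_key
from .stats import poisson_binomial_pmf, population_skewness_kurtosis

__all__ = [
    "Window",
    "HotspotNullModel",
    "MomentDiagnostics",
    "HotspotResult",
    "tile_genome",
    "count_window_samples",
    "per_sample_window_prob",
    "poisson_binomial_sf",
    "filter_problematic",
    "detect_hotspots",
    "window_size_sweep",
    "moment_diagnostics",
    "DEFAULT_EXCLUDED_CHROMS",
]

DEFAULT_EXCLUDED_CHROMS = frozenset({"chrY"})

# re-export: the survival function is part of this module's surface
from .stats import poisson_binomial_sf  # noqa: E402,F401


@dataclass
class Window:
    """A genome tile with its recurrence count and significance."""

    span: GenomicInterval
    k: int = 0
    p_value: Optional[float] = None
    filtered_reason: Optional[str] = None  # masked | repeat | excluded_chrom


@dataclass(frozen=True)
class MomentDiagnostics:
    skewness: float
    kurtosis: float  # non-excess (normal = 3)


@dataclass
class HotspotNullModel:
    """Per-sample probabilities of hitting a fixed window under uniformity."""

    probs: np.ndarray  # p_i per sample, aligned with sample_ids
    sample_ids: List[str]
    G: int
    w: int

    @classmethod
    def from_mutations(
        cls,
        mutations: Sequence[MutationRecord],
        chrom_sizes: ChromSizes,
        w: int,
        excluded_chroms: Iterable[str] = DEFAULT_EXCLUDED_CHROMS,
    ) -> "HotspotNullModel":
        """Build p_i from each sample's mutation total on non-excluded chromosomes."""
        excluded = set(excluded_chroms)
        G = sum(size for chrom, size in chrom_sizes.items() if chrom not in excluded)
        if G <= 0:
            raise ValueError("zero usable genome length after chromosome exclusion")
        totals: Dict[str, int] = {}
        for mut in mutations:
            chrom = mut.position.chrom
            if chrom in excluded or chrom not in chrom_sizes:
                continue
            totals[mut.sample_id] = totals.get(mut.sample_id, 0) + 1
        sample_ids = sorted(totals)
        probs = np.array(
            [per_sample_window_prob(totals[s], G, w) for s in sample_ids]
        )
        return cls(probs=probs, sample_ids=sample_ids, G=G, w=w)

    def sf_table(self) -> np.ndarray:
        """P(K >= k) for k = 0..n, computed once from the shared PMF."""
        pmf = poisson_binomial_pmf(self.probs)
        # reversed cumulative sum; clip for float safety
        tail = np.minimum(1.0, np.maximum(0.0, pmf[::-1].cumsum()[::-1]))
        return tail


@dataclass
class HotspotResult:
    hotspots: List[Window]
    n_windows_k_ge_min: int  # tested windows (count >= min_k) before filtering
    alpha: float
    alpha_effective: float
    null_model: HotspotNullModel
    n_filtered: int


def tile_genome(chrom_sizes: ChromSizes, w: int = 21) -> List[GenomicInterval]:
    """Non-overlapping consecutive tiles per chromosome; a trailing partial
    tile of width < w is dropped."""
    if w < 1:
        raise ValueError("window width must be >= 1")
    tiles: List[GenomicInterval] = []
    for chrom in sorted(chrom_sizes, key=chrom_sort_key):
        n = chrom_sizes[chrom] // w
        tiles.extend(GenomicInterval(chrom, i * w, (i + 1) * w) for i in range(n))
    return tiles


def count_window_samples(
    windows: Sequence[Window], mutations: Sequence[MutationRecord]
) -> None:
    """Set ``k`` = number of distinct samples with >= 1 mutation per window.

    Windows are assumed to be fixed-width genome tiles, so a mutation maps to
    its window by integer division.  Mutations on chromosomes absent from the
    window set trigger a warning and are skipped.
    """
    if not windows:
        return
    w = windows[0].span.width
    index: Dict[Tuple[str, int], Window] = {}
    for win in windows:
        if win.span.width != w:
            raise ValueError("all windows must share one width")
        if win.span.start % w:
            raise ValueError("windows must be aligned genome tiles")
        index[(win.span.chrom, win.span.start // w)] = win
    known_chroms = {win.span.chrom for win in windows}
    hits: Set[Tuple[str, int, str]] = set()
    warned: Set[str] = set()
    for mut in mutations:
        chrom = mut.position.chrom
        if chrom not in known_chroms:
            if chrom not in warned:
                warnings.warn(f"mutation on unknown chromosome {chrom}; skipped")
                warned.add(chrom)
            continue
        key = (chrom, mut.position.start // w)
        if key in index:  # trailing-partial positions have no window
            hits.add((*key, mut.sample_id))
    counts: Dict[Tuple[str, int], int] = {}
    for chrom, widx, _sample in hits:
        counts[(chrom, widx)] = counts.get((chrom, widx), 0) + 1
    for win in windows:
        win.k = counts.get((win.span.chrom, win.span.start // w), 0)


def per_sample_window_prob(m_i: int, G: int, w: int) -> float:
    """Probability that a fixed w-bp window holds >= 1 of m_i uniform mutations.

    ``1 - (1 - w/G)**m_i`` -- treats placements as independent uniform drops,
    the same assumption the Poisson-binomial null makes across samples.
    """
    if m_i < 0:
        raise ValueError("mutation count must be >= 0")
    if not (1 <= w <= G):
        raise ValueError("require 1 <= w <= G")
    return 1.0 - (1.0 - w / G) ** m_i


def _flag_overlaps(
    windows: Sequence[Window],
    track: Sequence[GenomicInterval],
    reason: str,
) -> None:
    from intervaltree import IntervalTree

    trees: Dict[str, IntervalTree] = {}
    for iv in track:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    for win in windows:
        if win.filtered_reason is not None:
            continue
        tree = trees.get(win.span.chrom)
        if tree is not None and tree.overlap(win.span.start, win.span.end):
            win.filtered_reason = reason


def filter_problematic(
    windows: Sequence[Window],
    masked: Sequence[GenomicInterval] = (),
    repeats: Sequence[GenomicInterval] = (),
    excluded_chroms: Iterable[str] = DEFAULT_EXCLUDED_CHROMS,
) -> None:
    """Flag windows overlapping masked/repeat tracks (>= 1 bp) or lying on an
    excluded chromosome.  Flagged windows never appear in hotspot output."""
    excluded = set(excluded_chroms)
    for win in windows:
        if win.span.chrom in excluded:
            win.filtered_reason = "excluded_chrom"
    _flag_overlaps(windows, masked, "masked")
    _flag_overlaps(windows, repeats, "repeat")


def detect_hotspots(
    mutations: Sequence[MutationRecord],
    chrom_sizes: ChromSizes,
    masked: Sequence[GenomicInterval] = (),
    repeats: Sequence[GenomicInterval] = (),
    w: int = 21,
    alpha: float = 0.001,
    min_k: int = 1,
    bonferroni: bool = False,
    excluded_chroms: Iterable[str] = DEFAULT_EXCLUDED_CHROMS,
) -> HotspotResult:
    """Full hotspot pipeline: tile, count, score, filter, select.

    P-values come from the Poisson-binomial null built from ALL samples'
    mutation totals.  With ``bonferroni=True`` the selection threshold becomes
    ``alpha / n_tested`` where n_tested is the number of windows with
    ``k >= min_k`` (counted before problematic-region filtering).  Returns
    hotspots sorted by p-value then coordinate.
    """
    if not mutations:
        raise ValueError("need at least one mutation record")
    excluded = set(excluded_chroms)
    null = HotspotNullModel.from_mutations(mutations, chrom_sizes, w, excluded)

    # count distinct samples per occupied window without materializing the
    # full genome tiling
    hits: Set[Tuple[str, int, str]] = set()
    for mut in mutations:
        chrom = mut.position.chrom
        if chrom not in chrom_sizes:
            warnings.warn(f"mutation on unknown chromosome {chrom}; skipped")
            continue
        widx = mut.position.start // w
        if (widx + 1) * w <= chrom_sizes[chrom]:  # inside a full tile
            hits.add((chrom, widx, mut.sample_id))
    counts: Dict[Tuple[str, int], int] = {}
    for chrom, widx, _sample in hits:
        counts[(chrom, widx)] = counts.get((chrom, widx), 0) + 1

    candidates = [
        Window(span=GenomicInterval(chrom, widx * w, (widx + 1) * w), k=k)
        for (chrom, widx), k in counts.items()
        if k >= min_k
    ]
    n_tested = len(candidates)
    if n_tested == 0:
        return HotspotResult([], 0, alpha, alpha, null, 0)

    sf = null.sf_table()
    nmax = len(null.probs)
    for win in candidates:
        win.p_value = float(sf[win.k]) if win.k <= nmax else 0.0

    filter_problematic(candidates, masked, repeats, excluded)
    n_filtered = sum(1 for win in candidates if win.filtered_reason is not None)

    alpha_eff = alpha / n_tested if bonferroni else alpha
    hotspots = [
        win
        for win in candidates
        if win.filtered_reason is None and win.p_value < alpha_eff
    ]
    hotspots.sort(
        key=lambda win: (win.p_value, chrom_sort_key(win.span.chrom), win.span.start)
    )
    return HotspotResult(hotspots, n_tested, alpha, alpha_eff, null, n_filtered)


def window_size_sweep(
    mutations: Sequence[MutationRecord],
    chrom_sizes: ChromSizes,
    sizes: Sequence[int] = (9, 21, 50, 5000),
) -> Dict[int, Dict]:
    """Distribution of per-window sample counts k for several window widths.

    For each width: histogram of k over occupied (k >= 1) windows plus
    mean and max.  When one width divides another the tiles nest, so max k
    is non-decreasing between those widths.
    """
    out: Dict[int, Dict] = {}
    for w in sizes:
        if w < 1:
            raise ValueError("window sizes must be >= 1")
        hits: Set[Tuple[str, int, str]] = set()
        for mut in mutations:
            chrom = mut.position.chrom
            if chrom not in chrom_sizes:
                continue
            widx = mut.position.start // w
            if (widx + 1) * w <= chrom_sizes[chrom]:
                hits.add((chrom, widx, mut.sample_id))
        counts: Dict[Tuple[str, int], int] = {}
        for chrom, widx, _sample in hits:
            counts[(chrom, widx)] = counts.get((chrom, widx), 0) + 1
        ks = list(counts.values())
        hist: Dict[int, int] = {}
        for k in ks:
            hist[k] = hist.get(k, 0) + 1
        out[w] = {
            "hist": dict(sorted(hist.items())),
            "mean": float(np.mean(ks)) if ks else 0.0,
            "max": max(ks) if ks else 0,
            "n_occupied": len(ks),
        }
    return out


def moment_diagnostics(values: Sequence[float]) -> MomentDiagnostics:
    """Population skewness and (non-excess) kurtosis of a sample, as used to
    eyeball which count distribution fits the occupied-window k values."""
    skew, kurt = population_skewness_kurtosis(values)
    return MomentDiagnostics(skewness=skew, kurtosis=kurt)
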