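"""Log-binned tract-length profiles: the inference summary statistic.

A profile is a (bins x 3 ancestries x 2 chromosome-classes) matrix of
tract counts: 22 length windows on a geometric (sqrt-2) grid from 0.2 cM
to 204.8 cM, the three ancestries, and autosomes vs X. Per-individual
integer counts are averaged across a population (the permutation-
invariant reduction), optionally normalised per chromosome-class slab,
and flattened into the network feature vector.

The X slab uses females only by default: male X calls are excluded to
avoid hemizygosity artefacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .forward_simulator import Individual, Population, FEMALE

__all__ = [
    "N_BINS",
    "AUTOSOME",
    "XCHROM",
    "bin_edges",
    "bin_labels",
    "TractLengthProfile",
    "individual_profile",
    "individual_profile_from_lengths",
    "population_profile",
    "per_individual_counts",
    "population_counts_from_segments",
    "pop_mean_counts",
    "normalize_profile",
    "bootstrap_profile",
    "flatten",
    "unflatten",
    "profile_to_frame",
    "profile_from_frame",
]

N_BINS = 22
AUTOSOME = 0
XCHROM = 1


def bin_edges() -> np.ndarray:
    """The 21 interior breakpoints b_k = 2**((k+1)/2) / 10 cM, k = 1..21.

    They delimit 22 windows: [0, 0.2), [0.2, 0.2*sqrt(2)), ...,
    [204.8, inf); binning is lower-inclusive / upper-exclusive.
    """
    k = np.arange(1, 22)
    return 2.0 ** ((k + 1) / 2.0) / 10.0


def bin_labels(no_shortest: bool = False) -> list[str]:
    edges = bin_edges()
    lows = np.concatenate([[0.0], edges])
    highs = np.concatenate([edges, [np.inf]])
    labels = [f"[{lo:g},{hi:g})" for lo, hi in zip(lows, highs)]
    return labels[1:] if no_shortest else labels


@dataclass(frozen=True)
class TractLengthProfile:
    """Counts (or normalised values) per (length bin, ancestry, class).

    ``counts`` has shape (n_bins, 3, 2) with class 0 = autosomes and
    class 1 = X. ``n_individuals`` records how many individuals were
    averaged (1 for a per-individual profile).
    """

    counts: np.ndarray
    normalization: str = "raw"
    windows: str = "all_windows"
    n_individuals: int = 1

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        n_bins = N_BINS if self.windows == "all_windows" else N_BINS - 1
        if self.windows not in ("all_windows", "no_shortest"):
            raise ValueError("windows must be 'all_windows' or 'no_shortest'")
        if self.normalization not in ("raw", "divided_by_total"):
            raise ValueError("normalization must be 'raw' or 'divided_by_total'")
        if counts.shape != (n_bins, 3, 2):
            raise ValueError(
                f"counts must have shape ({n_bins}, 3, 2), got {counts.shape}"
            )
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def slab(self, chrom_class: int) -> np.ndarray:
        return self.counts[:, :, chrom_class]

    def total(self, chrom_class: int) -> float:
        return float(self.slab(chrom_class).sum())


def _bin_index(lengths: np.ndarray, edges: np.ndarray) -> np.ndarray:
    # side='right' makes each window lower-inclusive / upper-exclusive
    return np.searchsorted(edges, lengths, side="right")


def individual_profile_from_lengths(
    lengths_by_cell: dict[tuple[int, int], np.ndarray],
    edges: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Raw (22, 3, 2) counts from tract lengths keyed by (ancestry, class)."""
    edges = bin_edges() if edges is None else edges
    counts = np.zeros((N_BINS, 3, 2))
    for (anc, cls), lengths in lengths_by_cell.items():
        lengths = np.asarray(lengths, dtype=float)
        if lengths.size == 0:
            continue
        idx = _bin_index(lengths, edges)
        np.add.at(counts[:, anc - 1, cls], idx, 1.0)
    return counts


def individual_profile(
    individual: Individual,
    edges: Optional[np.ndarray] = None,
    female_x_only: bool = True,
    x_index: Optional[int] = None,
) -> TractLengthProfile:
    """Integer tract counts of one individual over all carried haplotypes.

    ``x_index`` locates the X chromosome in the individual's haplotype
    list (``GeneticMap.x_index``); ``None`` means no X is present.
    """
    edges = bin_edges() if edges is None else edges
    return TractLengthProfile(
        _individual_counts(individual, x_index, edges, female_x_only)
    )


def _x_index_of(pop: Population) -> Optional[int]:
    return pop.gmap.x_index


def _individual_counts(
    individual: Individual,
    x_index: Optional[int],
    edges: np.ndarray,
    female_x_only: bool,
) -> np.ndarray:
    counts = np.zeros((N_BINS, 3, 2))
    for i, haps in enumerate(individual.haplotypes):
        cls = XCHROM if i == x_index else AUTOSOME
        if cls == XCHROM and female_x_only and individual.sex != FEMALE:
            continue
        for h in haps:
            lengths = h.tract_lengths()
            idx = _bin_index(lengths, edges)
            anc_idx = h.ancestries.astype(int) - 1
            np.add.at(counts[:, :, cls], (idx, anc_idx), 1.0)
    return counts


def per_individual_counts(
    pop: Population,
    edges: Optional[np.ndarray] = None,
    female_x_only: bool = True,
) -> np.ndarray:
    """Stacked raw counts, shape (n_individuals, 22, 3, 2)."""
    edges = bin_edges() if edges is None else edges
    x = _x_index_of(pop)
    return np.stack(
        [_individual_counts(ind, x, edges, female_x_only) for ind in pop]
    )


def population_profile(
    individuals: Population | Sequence[Individual],
    edges: Optional[np.ndarray] = None,
    female_x_only: bool = True,
    x_index: Optional[int] = None,
) -> TractLengthProfile:
    """Element-wise mean of per-individual counts (X over females only).

    Accepts a :class:`Population` (X located via its map) or a bare
    sequence of individuals with an explicit ``x_index``.
    """
    edges = bin_edges() if edges is None else edges
    if isinstance(individuals, Population):
        x = _x_index_of(individuals)
        inds = individuals.individuals
    else:
        x = x_index
        inds = list(individuals)
    if not inds:
        raise ValueError("population_profile needs at least one individual")
    counts = np.stack([_individual_counts(i, x, edges, female_x_only) for i in inds])
    mean = counts[:, :, :, AUTOSOME].mean(axis=0)
    if female_x_only:
        fem = [j for j, i in enumerate(inds) if i.sex == FEMALE]
        x_mean = (
            counts[fem][:, :, :, XCHROM].mean(axis=0) if fem else np.zeros((N_BINS, 3))
        )
    else:
        x_mean = counts[:, :, :, XCHROM].mean(axis=0)
    out = np.stack([mean, x_mean], axis=-1)
    return TractLengthProfile(out, n_individuals=len(inds))


def normalize_profile(
    profile: TractLengthProfile,
    mode: str = "divided_by_total",
    windows: str = "all_windows",
) -> TractLengthProfile:
    """Apply the window/scaling variants used for network input.

    ``no_shortest`` drops the first (<0.2 cM) window before any division;
    ``divided_by_total`` scales the autosome and X slabs independently so
    each sums to one. An all-zero slab is left as zeros with a warning.
    """
    if profile.normalization != "raw":
        raise ValueError("normalize_profile expects a raw profile")
    counts = profile.counts
    if windows == "no_shortest":
        counts = counts[1:]
    elif windows != "all_windows":
        raise ValueError("windows must be 'all_windows' or 'no_shortest'")
    if mode == "raw":
        return TractLengthProfile(
            counts, "raw", windows, n_individuals=profile.n_individuals
        )
    if mode != "divided_by_total":
        raise ValueError("mode must be 'raw' or 'divided_by_total'")
    out = counts.astype(float).copy()
    for cls in (AUTOSOME, XCHROM):
        total = out[:, :, cls].sum()
        if total > 0:
            out[:, :, cls] /= total
        else:
            warnings.warn(f"chromosome class {cls}: zero total, slab left as zeros")
    return TractLengthProfile(
        out, "divided_by_total", windows, n_individuals=profile.n_individuals
    )


def pop_mean_counts(
    per_ind_counts: np.ndarray, female_mask: Optional[np.ndarray] = None
) -> np.ndarray:
    """Population mean: autosome slab over everyone, X slab over females.

    ``female_mask`` marks which rows are female; ``None`` averages the X
    slab over all rows (appropriate when males' X slabs were excluded
    upstream or the input is female-only).
    """
    counts = np.asarray(per_ind_counts, dtype=float)
    auto = counts[:, :, :, AUTOSOME].mean(axis=0)
    if female_mask is None:
        x = counts[:, :, :, XCHROM].mean(axis=0)
    else:
        fem = np.asarray(female_mask, dtype=bool)
        x = (
            counts[fem][:, :, :, XCHROM].mean(axis=0)
            if fem.any()
            else np.zeros(counts.shape[1:3])
        )
    return np.stack([auto, x], axis=-1)


def bootstrap_profile(
    per_ind_counts: np.ndarray,
    B: int = 1000,
    rng: Optional[np.random.Generator] = None,
    female_mask: Optional[np.ndarray] = None,
) -> tuple[TractLengthProfile, np.ndarray]:
    """Bootstrap each individual's per-(ancestry, class) histogram.

    For every individual and every (ancestry, chromosome-class) cell
    column, the tract bin labels are resampled with replacement ``B``
    times; the per-individual bootstrap mean replaces the observed
    histogram and the population mean is taken afterwards (X slab over
    ``female_mask`` when given).

    Returns the population-mean bootstrap profile and the ``B``
    population-mean resampled profiles (shape (B, bins, 3, 2)).
    """
    rng = np.random.default_rng() if rng is None else rng
    counts = np.asarray(per_ind_counts, dtype=float)
    if counts.ndim != 4:
        raise ValueError("expected (n_individuals, bins, 3, 2) counts")
    n_ind, n_bins = counts.shape[0], counts.shape[1]
    resamples = np.zeros((B, n_ind, n_bins, 3, 2))
    for i in range(n_ind):
        for anc in range(3):
            for cls in (AUTOSOME, XCHROM):
                hist = counts[i, :, anc, cls]
                total = int(round(hist.sum()))
                if total == 0:
                    continue
                p = hist / hist.sum()
                resamples[:, i, :, anc, cls] = rng.multinomial(total, p, size=B)
    boot_pop = np.stack(
        [pop_mean_counts(resamples[b], female_mask) for b in range(B)]
    )
    mean = boot_pop.mean(axis=0)
    return (
        TractLengthProfile(mean, n_individuals=n_ind),
        boot_pop,
    )


_X_CHROM_NAMES = frozenset({"X", "chrX", "23", "chr23"})


def population_counts_from_segments(
    segments,
    edges: Optional[np.ndarray] = None,
    x_chrom_names=_X_CHROM_NAMES,
    sex_of: Optional[dict] = None,
    female_x_only: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Per-sample raw counts from :class:`~.local_ancestry_io.SegmentRecord` lists.

    Chromosomes named in ``x_chrom_names`` feed the X slab; when a
    ``sex_of`` mapping is supplied and ``female_x_only`` is set, male X
    segments are dropped. Returns (counts (n_samples, 22, 3, 2), samples).
    """
    edges = bin_edges() if edges is None else edges
    samples: dict[str, int] = {}
    for seg in segments:
        samples.setdefault(seg.sample, len(samples))
    counts = np.zeros((len(samples), N_BINS, 3, 2))
    for seg in segments:
        cls = XCHROM if seg.chrom in x_chrom_names else AUTOSOME
        if (
            cls == XCHROM
            and female_x_only
            and sex_of is not None
            and sex_of.get(seg.sample, "F") != FEMALE
        ):
            continue
        b = int(_bin_index(np.array([seg.length_cm]), edges)[0])
        counts[samples[seg.sample], b, seg.ancestry - 1, cls] += 1.0
    return counts, list(samples)


def flatten(profile: TractLengthProfile) -> np.ndarray:
    """Row-major (bin, ancestry, class) feature vector: 132 or 126 values."""
    return profile.counts.reshape(-1).copy()


def unflatten(
    vector: np.ndarray,
    windows: str = "all_windows",
    normalization: str = "divided_by_total",
) -> TractLengthProfile:
    n_bins = N_BINS if windows == "all_windows" else N_BINS - 1
    v = np.asarray(vector, dtype=float)
    if v.size != n_bins * 6:
        raise ValueError(f"expected {n_bins * 6} values, got {v.size}")
    return TractLengthProfile(v.reshape(n_bins, 3, 2), normalization, windows)


def profile_to_frame(profile: TractLengthProfile) -> pd.DataFrame:
    """Long-format table: bin, bin_label, ancestry, chrom_class, value."""
    labels = bin_labels(profile.windows == "no_shortest")
    rows = []
    for b in range(profile.n_bins):
        for anc in range(3):
            for cls, cls_name in ((AUTOSOME, "autosome"), (XCHROM, "X")):
                rows.append(
                    {
                        "bin": b,
                        "bin_label": labels[b],
                        "ancestry": anc + 1,
                        "chrom_class": cls_name,
                        "value": profile.counts[b, anc, cls],
                    }
                )
    return pd.DataFrame(rows)


def profile_from_frame(df: pd.DataFrame) -> TractLengthProfile:
    n_bins = df["bin"].max() + 1
    windows = "all_windows" if n_bins == N_BINS else "no_shortest"
    counts = np.zeros((n_bins, 3, 2))
    cls_map = {"autosome": AUTOSOME, "X": XCHROM}
    for _, row in df.iterrows():
        counts[int(row["bin"]), int(row["ancestry"]) - 1, cls_map[row["chrom_class"]]] = row[
            "value"
        ]
    norm = "raw"
    for cls in (AUTOSOME, XCHROM):
        if abs(counts[:, :, cls].sum() - 1.0) < 1e-6:
            norm = "divided_by_total"
    return TractLengthProfile(counts, norm, windows)
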