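"""Forward-in-time simulation of local-ancestry tracts under the mating model.

The simulator tracks, for every individual, the ancestry of each genomic
segment on 22 autosomes plus the X chromosome (configurable), working
entirely in genetic-map units (cM). Haplotypes are run-length encoded:
an array of tract end positions and an array of ancestry codes. Females
carry two X copies, males one; the male X is transmitted to daughters
without recombination, so females and males contribute 2/3 and 1/3 of the
X gene pool respectively.

Generations are non-overlapping with a constant, even population size and
an exact half/half sex ratio. Each offspring results from one mating
event: with probability 1/2 a uniformly chosen female initiates and her
partner is drawn from the kernel-weighted conditional over all males
(symmetrically for a male initiator).

Lengths in the underlying physical genome are assumed to be scaled down
(default factor 1000) purely for bookkeeping parity with sequence-level
simulators; all genetics here is computed in unscaled cM, so the factor
does not change any statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .mating_model import (
    AncestryVector,
    GaussianMatingKernel,
    MatingParams,
    build_kernel,
)

__all__ = [
    "ChromosomeMap",
    "GeneticMap",
    "Tract",
    "Haplotype",
    "Individual",
    "Population",
    "ScenarioConfig",
    "SimulationResult",
    "read_hapmap",
    "write_hapmap",
    "largest_remainder_counts",
    "make_founder",
    "found_population",
    "ancestry_proportions",
    "meiosis",
    "step_generation",
    "apply_pulse",
    "run_scenario",
]

FEMALE = "F"
MALE = "M"


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChromosomeMap:
    """One chromosome of the genetic map.

    ``positions_bp``/``map_cm`` give an optional monotone physical-to-
    genetic interpolation table (HapMap style); only ``length_cm`` is used
    by the simulator itself.
    """

    name: str
    length_cm: float
    is_x: bool = False
    positions_bp: Optional[np.ndarray] = None
    map_cm: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.length_cm <= 0:
            raise ValueError(f"chromosome {self.name}: length must be > 0 cM")
        if (self.positions_bp is None) != (self.map_cm is None):
            raise ValueError("positions_bp and map_cm must be given together")
        if self.map_cm is not None:
            m = np.asarray(self.map_cm, dtype=float)
            if np.any(np.diff(m) < 0):
                raise ValueError(f"chromosome {self.name}: genetic map not monotone")

    def phys_to_genetic(self, pos_bp) -> np.ndarray:
        if self.positions_bp is None:
            raise ValueError("no physical map attached")
        return np.interp(pos_bp, self.positions_bp, self.map_cm)


@dataclass(frozen=True)
class GeneticMap:
    """An ordered collection of chromosome maps (autosomes then X)."""

    chromosomes: tuple[ChromosomeMap, ...]

    def __post_init__(self):
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))
        if not self.chromosomes:
            raise ValueError("genetic map needs at least one chromosome")

    def __len__(self):
        return len(self.chromosomes)

    def __iter__(self):
        return iter(self.chromosomes)

    def __getitem__(self, i) -> ChromosomeMap:
        return self.chromosomes[i]

    @property
    def autosome_indices(self) -> list[int]:
        return [i for i, c in enumerate(self.chromosomes) if not c.is_x]

    @property
    def x_index(self) -> Optional[int]:
        xs = [i for i, c in enumerate(self.chromosomes) if c.is_x]
        if len(xs) > 1:
            raise ValueError("more than one X chromosome in map")
        return xs[0] if xs else None

    @property
    def lengths_cm(self) -> np.ndarray:
        return np.array([c.length_cm for c in self.chromosomes])

    def by_name(self, name: str) -> int:
        for i, c in enumerate(self.chromosomes):
            if c.name == name:
                return i
        raise KeyError(name)


def read_hapmap(path) -> GeneticMap:
    """Read a HapMap-style recombination map.

    Whitespace-delimited text with a header and columns
    ``chrom position rate(cM/Mb) map(cM)``; rows grouped by chromosome.
    Chromosomes named ``X``/``chrX`` are flagged as the X.
    """
    chroms: dict[str, list[tuple[float, float]]] = {}
    order: list[str] = []
    with open(path) as fh:
        header = fh.readline()
        if not header:
            raise ValueError(f"{path}: empty map file")
        for lineno, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            chrom = parts[0]
            if chrom not in chroms:
                chroms[chrom] = []
                order.append(chrom)
            chroms[chrom].append((float(parts[1]), float(parts[3])))
    out = []
    for name in order:
        rows = chroms[name]
        pos = np.array([r[0] for r in rows])
        cm = np.array([r[1] for r in rows])
        is_x = name.lstrip("chr").upper() == "X"
        out.append(
            ChromosomeMap(
                name=name,
                length_cm=float(cm[-1]),
                is_x=is_x,
                positions_bp=pos,
                map_cm=cm,
            )
        )
    return GeneticMap(tuple(out))


def write_hapmap(gmap: GeneticMap, path) -> None:
    """Write a map in the format accepted by :func:`read_hapmap`.

    Uniform-rate chromosomes without a physical table are written as two
    rows assuming 1 Mb per cM.
    """
    with open(path, "w") as fh:
        fh.write("chrom\tposition\trate_cM_Mb\tmap_cM\n")
        for c in gmap:
            if c.positions_bp is not None:
                pos, cm = c.positions_bp, c.map_cm
            else:
                pos = np.array([0.0, c.length_cm * 1e6])
                cm = np.array([0.0, c.length_cm])
            rates = np.append(np.diff(cm) / (np.diff(pos) / 1e6), 0.0)
            for p, r, m in zip(pos, rates, cm):
                fh.write(f"{c.name}\t{p:.0f}\t{r:.8g}\t{m:.8g}\n")


# ---------------------------------------------------------------------------
# Haplotypes and individuals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Tract:
    """A maximal single-ancestry segment on one chromosome copy (cM)."""

    start_cm: float
    end_cm: float
    ancestry: int

    def __post_init__(self):
        if not self.start_cm < self.end_cm:
            raise ValueError("tract must have start < end")
        if self.ancestry not in (1, 2, 3):
            raise ValueError("ancestry must be 1, 2 or 3")

    @property
    def length_cm(self) -> float:
        return self.end_cm - self.start_cm


class Haplotype:
    """Run-length encoded ancestry along one chromosome copy.

    ``breaks`` holds the right edge (cM) of each tract, ending at the
    chromosome length; ``ancestries`` the matching ancestry codes.
    Adjacent tracts always differ in ancestry (maximal merging).
    """

    __slots__ = ("breaks", "ancestries")

    def __init__(self, breaks, ancestries):
        self.breaks = np.asarray(breaks, dtype=np.float64)
        self.ancestries = np.asarray(ancestries, dtype=np.int8)
        if self.breaks.shape != self.ancestries.shape or self.breaks.ndim != 1:
            raise ValueError("breaks and ancestries must be 1-D and equal length")

    def _init_fast(self, breaks: np.ndarray, ancestries: np.ndarray) -> "Haplotype":
        # hot-path constructor: arrays already well-typed (from _recombine)
        self.breaks = breaks
        self.ancestries = ancestries
        return self

    @classmethod
    def uniform(cls, ancestry: int, length_cm: float) -> "Haplotype":
        return cls([length_cm], [ancestry])

    @property
    def length_cm(self) -> float:
        return float(self.breaks[-1])

    @property
    def n_tracts(self) -> int:
        return len(self.breaks)

    def tracts(self) -> list[Tract]:
        out = []
        start = 0.0
        for end, anc in zip(self.breaks, self.ancestries):
            out.append(Tract(start, float(end), int(anc)))
            start = float(end)
        return out

    def tract_lengths(self) -> np.ndarray:
        lens = self.breaks.copy()
        lens[1:] -= self.breaks[:-1]
        return lens

    def ancestry_lengths(self) -> np.ndarray:
        """Total cM carried per ancestry (length-3 vector)."""
        return _ancestry_lengths3(self.breaks, self.ancestries)

    def validate(self, length_cm: float) -> None:
        if abs(self.length_cm - length_cm) > 1e-9:
            raise ValueError("haplotype does not tile the chromosome")
        if np.any(np.diff(self.breaks) <= 0):
            raise ValueError("tract breaks not strictly increasing")
        if np.any(self.ancestries[1:] == self.ancestries[:-1]):
            raise ValueError("adjacent tracts share an ancestry (not maximal)")

    def __eq__(self, other):
        return (
            isinstance(other, Haplotype)
            and np.array_equal(self.breaks, other.breaks)
            and np.array_equal(self.ancestries, other.ancestries)
        )

    def copy(self) -> "Haplotype":
        return Haplotype(self.breaks.copy(), self.ancestries.copy())


def _recombine_py(b0, a0, b1, a1, xos, first):
    """Merge two parental haplotypes given sorted crossover positions.

    Segments between consecutive crossovers are copied alternately from
    the two haplotypes starting with ``first``; the output is
    maximal-merged. Numba-compatible.
    """
    L = b0[-1]
    n_max = b0.shape[0] + b1.shape[0] + 2 * xos.shape[0] + 2
    out_b = np.empty(n_max, dtype=np.float64)
    out_a = np.empty(n_max, dtype=np.int8)
    m = 0
    src = first
    prev = 0.0
    k = 0
    n_xo = xos.shape[0]
    while prev < L:
        seg_end = xos[k] if k < n_xo else L
        if src == 0:
            b, a = b0, a0
        else:
            b, a = b1, a1
        i = 0
        while b[i] <= prev:
            i += 1
        while prev < seg_end:
            e = b[i] if b[i] < seg_end else seg_end
            anc = a[i]
            if m > 0 and out_a[m - 1] == anc:
                out_b[m - 1] = e
            else:
                out_b[m] = e
                out_a[m] = anc
                m += 1
            prev = e
            i += 1
        src = 1 - src
        k += 1
    return out_b[:m], out_a[:m]


def _ancestry_lengths3_py(breaks, ancs):
    out = np.zeros(3)
    prev = 0.0
    for i in range(breaks.shape[0]):
        out[ancs[i] - 1] += breaks[i] - prev
        prev = breaks[i]
    return out


def _recombine_into_py(breaks, ancs, s0, e0, s1, e1, xos, first, out_b, out_a, m):
    """In-place variant of :func:`_recombine_py` on packed flat arrays.

    Haplotype 0 lives at ``breaks[s0:e0]`` etc.; the merged gamete is
    written at cursor ``m`` of the output arrays. Returns the new cursor.
    """
    L = breaks[e0 - 1]
    src = first
    prev = 0.0
    k = 0
    n_xo = xos.shape[0]
    m0 = m
    while prev < L:
        seg_end = xos[k] if k < n_xo else L
        if src == 0:
            lo, hi = s0, e0
        else:
            lo, hi = s1, e1
        i = lo
        while breaks[i] <= prev:
            i += 1
        while prev < seg_end:
            bi = breaks[i]
            e = bi if bi < seg_end else seg_end
            anc = ancs[i]
            if m > m0 and out_a[m - 1] == anc:
                out_b[m - 1] = e
            else:
                out_b[m] = e
                out_a[m] = anc
                m += 1
            prev = e
            i += 1
        src = 1 - src
        k += 1
    return m


def _step_kernel_py(
    breaks,
    ancs,
    hap_off,
    hap_ptr,
    mothers,
    fathers,
    child_is_male,
    x_index,
    lengths,
    counts,
    firsts,
    pos,
    pos_off,
):
    """Produce all offspring haplotypes of one generation on packed arrays.

    ``hap_ptr[i, c, p]`` is the flat haplotype id of copy ``p`` of
    chromosome ``c`` of parent ``i`` (-1 when absent, i.e. male X);
    haplotype ``h`` occupies ``breaks[hap_off[h]:hap_off[h+1]]``.
    Randomness rows: ``2j`` maternal, ``2j+1`` paternal meiosis of
    offspring ``j``. Returns the packed child population plus ancestry
    proportions.
    """
    n = mothers.shape[0]
    C = lengths.shape[0]
    # upper bound on output tract count
    bound = 0
    for j in range(n):
        for r in range(2):
            parent = mothers[j] if r == 0 else fathers[j]
            row = 2 * j + r
            for c in range(C):
                if r == 1 and c == x_index and child_is_male[j]:
                    continue
                h0 = hap_ptr[parent, c, 0]
                h1 = hap_ptr[parent, c, 1]
                l0 = hap_off[h0 + 1] - hap_off[h0]
                l1 = l0 if h1 < 0 else hap_off[h1 + 1] - hap_off[h1]
                bound += l0 + l1 + counts[row, c] + 2
    out_b = np.empty(bound, dtype=np.float64)
    out_a = np.empty(bound, dtype=np.int8)
    child_hap_off = np.empty(2 * n * C + 1, dtype=np.int64)
    child_hap_off[0] = 0
    child_hap_ptr = np.full((n, C, 2), -1, dtype=np.int64)
    props = np.zeros((n, 3))
    m = 0
    nh = 0
    for j in range(n):
        for r in range(2):
            parent = mothers[j] if r == 0 else fathers[j]
            row = 2 * j + r
            for c in range(C):
                if r == 1 and c == x_index and child_is_male[j]:
                    continue
                h0 = hap_ptr[parent, c, 0]
                h1 = hap_ptr[parent, c, 1]
                g0 = m
                if h1 < 0:
                    # male X: transmitted without recombination
                    for t in range(hap_off[h0], hap_off[h0 + 1]):
                        out_b[m] = breaks[t]
                        out_a[m] = ancs[t]
                        m += 1
                else:
                    k = counts[row, c]
                    if k == 0:
                        hsel = h0 if firsts[row, c] == 0 else h1
                        for t in range(hap_off[hsel], hap_off[hsel + 1]):
                            out_b[m] = breaks[t]
                            out_a[m] = ancs[t]
                            m += 1
                    else:
                        o = pos_off[row * C + c]
                        xos = np.sort(pos[o : o + k] * lengths[c])
                        m = _recombine_into(
                            breaks,
                            ancs,
                            hap_off[h0],
                            hap_off[h0 + 1],
                            hap_off[h1],
                            hap_off[h1 + 1],
                            xos,
                            firsts[row, c],
                            out_b,
                            out_a,
                            m,
                        )
                prev = 0.0
                for t in range(g0, m):
                    props[j, out_a[t] - 1] += out_b[t] - prev
                    prev = out_b[t]
                child_hap_ptr[j, c, r] = nh
                child_hap_off[nh + 1] = m
                nh += 1
    for j in range(n):
        total = props[j, 0] + props[j, 1] + props[j, 2]
        for s in range(3):
            props[j, s] /= total
    return out_b[:m], out_a[:m], child_hap_off[: nh + 1], child_hap_ptr, props


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _recombine = njit(cache=True)(_recombine_py)
    _ancestry_lengths3 = njit(cache=True)(_ancestry_lengths3_py)
    _recombine_into = njit(cache=True)(_recombine_into_py)
    _step_kernel = njit(cache=True)(_step_kernel_py)
except Exception:  # pragma: no cover
    _recombine = _recombine_py
    _ancestry_lengths3 = _ancestry_lengths3_py
    _recombine_into = _recombine_into_py
    _step_kernel = _step_kernel_py


class Individual:
    """A diploid (female) or X-hemizygous (male) genome as tract lists.

    ``haplotypes[i]`` is the list of :class:`Haplotype` copies of
    chromosome ``i`` of the map: two for each autosome, two X for a
    female, one X for a male.
    """

    __slots__ = ("sex", "haplotypes", "_proportions")

    def __init__(self, sex: str, haplotypes: list[list[Haplotype]], gmap: GeneticMap):
        if sex not in (FEMALE, MALE):
            raise ValueError("sex must be 'F' or 'M'")
        self.sex = sex
        self.haplotypes = haplotypes
        self._proportions = _proportions_from_haplotypes(haplotypes)
        if len(haplotypes) != len(gmap):
            raise ValueError("haplotype list does not match map")
        x = gmap.x_index
        for i, haps in enumerate(haplotypes):
            expected = 1 if (i == x and sex == MALE) else 2
            if len(haps) != expected:
                raise ValueError(
                    f"chromosome {i}: expected {expected} copies, got {len(haps)}"
                )

    @classmethod
    def _from_parts(cls, sex, haplotypes, proportions) -> "Individual":
        # hot-path constructor: inputs produced by meiosis are valid by
        # construction, so the per-chromosome checks are skipped
        self = object.__new__(cls)
        self.sex = sex
        self.haplotypes = haplotypes
        self._proportions = proportions
        return self

    @property
    def proportions(self) -> np.ndarray:
        """Genome-wide ancestry proportions (genetic-length weighted)."""
        return self._proportions

    def ancestry_vector(self) -> AncestryVector:
        return AncestryVector(tuple(self._proportions))

    def validate(self, gmap: GeneticMap) -> None:
        for i, haps in enumerate(self.haplotypes):
            for h in haps:
                h.validate(gmap[i].length_cm)

    def n_tracts(self) -> int:
        return sum(h.n_tracts for haps in self.haplotypes for h in haps)


def _proportions_from_haplotypes(haplotypes) -> np.ndarray:
    totals = np.zeros(3)
    for haps in haplotypes:
        for h in haps:
            totals += h.ancestry_lengths()
    return totals / totals.sum()


def ancestry_proportions(individual: Individual, gmap: GeneticMap) -> AncestryVector:
    """Genetic-length-weighted ancestry fractions over all carried copies."""
    return individual.ancestry_vector()


class Population:
    """One non-overlapping generation of individuals."""

    def __init__(self, individuals: Sequence[Individual], gmap: GeneticMap):
        self.individuals = list(individuals)
        self.gmap = gmap

    def __len__(self):
        return len(self.individuals)

    def __iter__(self):
        return iter(self.individuals)

    @property
    def females(self) -> list[Individual]:
        return [i for i in self.individuals if i.sex == FEMALE]

    @property
    def males(self) -> list[Individual]:
        return [i for i in self.individuals if i.sex == MALE]

    def proportions_matrix(self) -> np.ndarray:
        return np.stack([ind.proportions for ind in self.individuals])

    def mean_proportions(self) -> np.ndarray:
        return self.proportions_matrix().mean(axis=0)


# ---------------------------------------------------------------------------
# Scenario configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioConfig:
    """All demographic knobs of one simulation scenario."""

    genetic_map: GeneticMap
    founding_proportions: tuple[float, float, float]
    population_size: int = 1000
    generations: int = 19
    migration_model: str = "one_pulse"
    pulse_generation: int = 10
    physical_scaling: float = 1000.0

    def __post_init__(self):
        if self.population_size < 2 or self.population_size % 2:
            raise ValueError("population_size must be even and >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.migration_model not in ("one_pulse", "two_pulses"):
            raise ValueError("migration_model must be 'one_pulse' or 'two_pulses'")
        if self.migration_model == "two_pulses" and not (
            1 < self.pulse_generation < self.generations
        ):
            raise ValueError("pulse_generation must lie strictly inside (1, generations)")
        p = np.asarray(self.founding_proportions, dtype=float)
        if p.shape != (3,) or np.any(p < 0) or abs(p.sum() - 1) > 1e-6:
            raise ValueError("founding_proportions must be 3 non-negative values summing to 1")
        object.__setattr__(
            self, "founding_proportions", tuple(float(x) for x in p / p.sum())
        )


@dataclass
class SimulationResult:
    """Output of :func:`run_scenario`."""

    population: Population
    mean_proportions_by_generation: np.ndarray  # (generations + 1, 3)
    params: MatingParams
    config: ScenarioConfig
    seed: Optional[int] = None


# ---------------------------------------------------------------------------
# Founding
# ---------------------------------------------------------------------------

def largest_remainder_counts(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer counts summing to ``total``, proportional to ``weights``."""
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("weights must have positive sum")
    quota = w / w.sum() * total
    counts = np.floor(quota).astype(int)
    remainder = quota - counts
    short = total - counts.sum()
    for i in np.argsort(-remainder)[:short]:
        counts[i] += 1
    return counts


def make_founder(ancestry: int, sex: str, gmap: GeneticMap) -> Individual:
    """An unadmixed individual: single full-chromosome tracts."""
    x = gmap.x_index
    haps = []
    for i, c in enumerate(gmap):
        n = 1 if (i == x and sex == MALE) else 2
        haps.append([Haplotype.uniform(ancestry, c.length_cm) for _ in range(n)])
    return Individual(sex, haps, gmap)


def _founder_wave_weights(config: ScenarioConfig, params: MatingParams) -> np.ndarray:
    c = np.asarray(config.founding_proportions)
    if config.migration_model == "two_pulses":
        if params.gfr is None:
            raise ValueError("two_pulses scenario requires GFR parameters")
        g = np.asarray(params.gfr)
        w = (1.0 - g) * c
        if w.sum() <= 0:
            raise ValueError("GFR removes the entire founding wave")
        return w / w.sum()
    return c


def found_population(
    config: ScenarioConfig, params: MatingParams, rng: np.random.Generator
) -> Population:
    """Generation-0 cohort of unadmixed founders.

    Ancestry counts follow the founding proportions (first-wave
    proportions ``(1-GFR_s)c_s`` renormalised under two pulses) with
    largest-remainder rounding; sexes are an exact half/half random
    assignment independent of ancestry.
    """
    n = config.population_size
    weights = _founder_wave_weights(config, params)
    counts = largest_remainder_counts(weights, n)
    for s in range(3):
        if weights[s] > 0 and counts[s] == 0:
            warnings.warn(
                f"ancestry {s + 1} has positive founding weight but 0 founders at N={n}"
            )
    ancestries = np.repeat([1, 2, 3], counts)
    sexes = np.array([FEMALE] * (n // 2) + [MALE] * (n // 2))
    rng.shuffle(sexes)
    individuals = [
        make_founder(int(anc), str(sex), config.genetic_map)
        for anc, sex in zip(ancestries, sexes)
    ]
    return Population(individuals, config.genetic_map)


# ---------------------------------------------------------------------------
# Meiosis
# ---------------------------------------------------------------------------

def _gamete_haplotype(
    h0: Haplotype, h1: Haplotype, length_cm: float, rng: np.random.Generator
) -> Haplotype:
    n_xo = rng.poisson(length_cm / 100.0)
    first = int(rng.integers(2))
    if n_xo == 0:
        return (h0 if first == 0 else h1).copy()
    xos = rng.random(n_xo) * length_cm
    xos.sort()  # duplicates are measure-zero and cancel (double switch)
    b, a = _recombine(h0.breaks, h0.ancestries, h1.breaks, h1.ancestries, xos, first)
    return Haplotype(b, a)


def meiosis(
    parent: Individual,
    gmap: GeneticMap,
    rng: np.random.Generator,
    chrom_indices: Optional[Iterable[int]] = None,
) -> list[Haplotype]:
    """One gamete: a recombined haplotype per requested chromosome.

    Crossover counts are Poisson with mean equal to the chromosome length
    in Morgans, positions uniform in genetic distance, no interference.
    A male X (single copy) is returned unrecombined.
    """
    idx = range(len(gmap)) if chrom_indices is None else chrom_indices
    out = []
    for i in idx:
        haps = parent.haplotypes[i]
        if len(haps) == 1:  # male X: transmitted intact
            out.append(haps[0].copy())
        else:
            out.append(_gamete_haplotype(haps[0], haps[1], gmap[i].length_cm, rng))
    return out


# ---------------------------------------------------------------------------
# Mating and generation turnover
# ---------------------------------------------------------------------------

def _pair_log_density(kernel: GaussianMatingKernel, fem_p, male_p) -> np.ndarray:
    """Log mating affinity for every (female, male) pair: shape (F, M)."""
    d = male_p[None, :, :2] - fem_p[:, None, :2]
    return kernel.log_density(d)


def _draw_couples(
    kernel: GaussianMatingKernel,
    females: list[Individual],
    males: list[Individual],
    n_offspring: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample (mother, father) index pairs for ``n_offspring`` events."""
    if not females or not males:
        raise ValueError("both sex classes must be non-empty")
    fem_p = np.stack([f.proportions for f in females])
    male_p = np.stack([m.proportions for m in males])
    return _draw_couples_arrays(kernel, fem_p, male_p, n_offspring, rng)


def _draw_couples_arrays(
    kernel: GaussianMatingKernel,
    fem_p: np.ndarray,
    male_p: np.ndarray,
    n_offspring: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    logd = _pair_log_density(kernel, fem_p, male_p)
    w = np.exp(logd - logd.max())

    cum_f = np.cumsum(w, axis=1)  # female-initiated: rows over males
    cum_m = np.cumsum(w, axis=0)  # male-initiated: columns over females

    n_f, n_m = fem_p.shape[0], male_p.shape[0]
    fem_init = rng.random(n_offspring) < 0.5
    mothers = np.empty(n_offspring, dtype=np.int64)
    fathers = np.empty(n_offspring, dtype=np.int64)
    init_f = rng.integers(n_f, size=n_offspring)
    init_m = rng.integers(n_m, size=n_offspring)
    u = rng.random(n_offspring)
    for j in range(n_offspring):
        if fem_init[j]:
            i = init_f[j]
            row = cum_f[i]
            mothers[j] = i
            fathers[j] = np.searchsorted(row, u[j] * row[-1], side="right")
        else:
            i = init_m[j]
            col = cum_m[:, i]
            fathers[j] = i
            mothers[j] = np.searchsorted(col, u[j] * col[-1], side="right")
    np.clip(mothers, 0, n_f - 1, out=mothers)
    np.clip(fathers, 0, n_m - 1, out=fathers)
    return mothers, fathers


class _GenerationRandomness:
    """Pre-drawn meiosis randomness for one whole generation.

    Row ``2j`` holds the maternal meiosis of offspring ``j``, row
    ``2j + 1`` the paternal one; unused draws (e.g. a son's paternal X)
    are simply skipped, which leaves the remaining draws i.i.d.
    """

    __slots__ = ("counts", "firsts", "offsets", "pos")

    def __init__(self, n_offspring: int, lengths: np.ndarray, rng: np.random.Generator):
        n_chrom = len(lengths)
        lam = np.broadcast_to(lengths / 100.0, (2 * n_offspring, n_chrom))
        self.counts = rng.poisson(lam).astype(np.int64)
        self.firsts = rng.integers(0, 2, size=(2 * n_offspring, n_chrom))
        self.offsets = np.concatenate(
            [[0], np.cumsum(self.counts.ravel())]
        ).astype(np.int64)
        self.pos = rng.random(int(self.offsets[-1]))


class _PackedPop:
    """A generation as flat arrays, the in-memory form the kernel eats."""

    __slots__ = ("breaks", "ancs", "hap_off", "hap_ptr", "sexes", "props")

    def __init__(self, breaks, ancs, hap_off, hap_ptr, sexes, props):
        self.breaks = breaks
        self.ancs = ancs
        self.hap_off = hap_off
        self.hap_ptr = hap_ptr  # (n, C, 2), -1 = absent copy
        self.sexes = sexes  # int8: 0 = F, 1 = M
        self.props = props

    def __len__(self):
        return self.hap_ptr.shape[0]

    def mean_proportions(self) -> np.ndarray:
        return self.props.mean(axis=0)


def _pack_population(pop: Population) -> _PackedPop:
    gmap = pop.gmap
    n, C = len(pop), len(gmap)
    hap_ptr = np.full((n, C, 2), -1, dtype=np.int64)
    pieces_b, pieces_a, sizes = [], [], [0]
    nh = 0
    for i, ind in enumerate(pop):
        for c in range(C):
            for p, h in enumerate(ind.haplotypes[c]):
                hap_ptr[i, c, p] = nh
                pieces_b.append(h.breaks)
                pieces_a.append(h.ancestries)
                sizes.append(h.breaks.shape[0])
                nh += 1
    hap_off = np.cumsum(sizes).astype(np.int64)
    breaks = np.concatenate(pieces_b) if pieces_b else np.empty(0)
    ancs = np.concatenate(pieces_a) if pieces_a else np.empty(0, dtype=np.int8)
    sexes = np.array([0 if ind.sex == FEMALE else 1 for ind in pop], dtype=np.int8)
    props = np.stack([ind.proportions for ind in pop])
    return _PackedPop(breaks, ancs, hap_off, hap_ptr, sexes, props)


def _unpack_population(packed: _PackedPop, gmap: GeneticMap) -> Population:
    individuals = []
    for i in range(len(packed)):
        haps: list[list[Haplotype]] = []
        for c in range(len(gmap)):
            copies = []
            for p in range(2):
                h = packed.hap_ptr[i, c, p]
                if h < 0:
                    continue
                s, e = packed.hap_off[h], packed.hap_off[h + 1]
                copies.append(
                    Haplotype.__new__(Haplotype)._init_fast(
                        packed.breaks[s:e].copy(), packed.ancs[s:e].copy()
                    )
                )
            haps.append(copies)
        sex = FEMALE if packed.sexes[i] == 0 else MALE
        individuals.append(Individual._from_parts(sex, haps, packed.props[i].copy()))
    return Population(individuals, gmap)


def _pack_founders(
    ancestries: np.ndarray, sexes: np.ndarray, gmap: GeneticMap
) -> _PackedPop:
    """Unadmixed individuals (single full-chromosome tracts), packed."""
    n, C = len(ancestries), len(gmap)
    x = gmap.x_index
    lengths = gmap.lengths_cm
    hap_ptr = np.full((n, C, 2), -1, dtype=np.int64)
    b, a = [], []
    nh = 0
    for i in range(n):
        for c in range(C):
            copies = 1 if (c == x and sexes[i] == 1) else 2
            for p in range(copies):
                hap_ptr[i, c, p] = nh
                b.append(lengths[c])
                a.append(ancestries[i])
                nh += 1
    breaks = np.asarray(b, dtype=np.float64)
    ancs = np.asarray(a, dtype=np.int8)
    hap_off = np.arange(nh + 1, dtype=np.int64)
    props = np.zeros((n, 3))
    props[np.arange(n), ancestries - 1] = 1.0
    return _PackedPop(breaks, ancs, hap_off, hap_ptr, sexes.astype(np.int8), props)


def _concat_packed(a: _PackedPop, b: _PackedPop) -> _PackedPop:
    nh_a = a.hap_off.shape[0] - 1
    hap_ptr_b = b.hap_ptr.copy()
    hap_ptr_b[hap_ptr_b >= 0] += nh_a
    return _PackedPop(
        np.concatenate([a.breaks, b.breaks]),
        np.concatenate([a.ancs, b.ancs]),
        np.concatenate([a.hap_off, b.hap_off[1:] + a.hap_off[-1]]),
        np.concatenate([a.hap_ptr, hap_ptr_b]),
        np.concatenate([a.sexes, b.sexes]),
        np.concatenate([a.props, b.props]),
    )


def _offspring_sex_codes(n: int, rng: np.random.Generator) -> np.ndarray:
    """Exact half/half sex assignment as a random permutation (0=F, 1=M)."""
    codes = np.zeros(n, dtype=np.int8)
    codes[n // 2 :] = 1
    rng.shuffle(codes)
    return codes


def _offspring_sexes(n: int, rng: np.random.Generator) -> np.ndarray:
    return np.where(_offspring_sex_codes(n, rng) == 0, FEMALE, MALE)


def _step_packed(
    packed: _PackedPop,
    kernel: GaussianMatingKernel,
    gmap: GeneticMap,
    rng: np.random.Generator,
    child_sexes: np.ndarray,
) -> _PackedPop:
    fem_idx = np.flatnonzero(packed.sexes == 0)
    male_idx = np.flatnonzero(packed.sexes == 1)
    if fem_idx.size == 0 or male_idx.size == 0:
        raise ValueError("both sex classes must be non-empty")
    n = len(child_sexes)
    m_l, f_l = _draw_couples_arrays(
        kernel, packed.props[fem_idx], packed.props[male_idx], n, rng
    )
    mothers = fem_idx[m_l]
    fathers = male_idx[f_l]
    lengths = gmap.lengths_cm
    rand = _GenerationRandomness(n, lengths, rng)
    x = gmap.x_index
    out_b, out_a, hap_off, hap_ptr, props = _step_kernel(
        packed.breaks,
        packed.ancs,
        packed.hap_off,
        packed.hap_ptr,
        mothers,
        fathers,
        child_sexes == 1,
        -1 if x is None else x,
        lengths,
        rand.counts,
        rand.firsts,
        rand.pos,
        rand.offsets,
    )
    return _PackedPop(out_b, out_a, hap_off, hap_ptr, child_sexes.copy(), props)


def _pulse_packed(
    packed: _PackedPop,
    config: ScenarioConfig,
    params: MatingParams,
    kernel: GaussianMatingKernel,
    rng: np.random.Generator,
) -> _PackedPop:
    if params.gfr is None:
        raise ValueError("apply_pulse requires GFR parameters")
    n = config.population_size
    c = np.asarray(config.founding_proportions)
    migrant_weights = np.asarray(params.gfr) * c
    rho = migrant_weights.sum()
    if rho >= 1.0:
        raise ValueError("total pulse fraction rho >= 1 leaves no resident offspring")
    sexes = _offspring_sex_codes(n, rng)
    if rho <= 0:
        return _step_packed(packed, kernel, config.genetic_map, rng, sexes)
    n_migrants = int(round(rho * n))
    counts = largest_remainder_counts(migrant_weights, n_migrants)
    migrant_ancestries = np.repeat(np.array([1, 2, 3], dtype=np.int8), counts)
    migrants = _pack_founders(
        migrant_ancestries, sexes[:n_migrants], config.genetic_map
    )
    residents = _step_packed(
        packed, kernel, config.genetic_map, rng, sexes[n_migrants:]
    )
    return _concat_packed(migrants, residents)


def step_generation(
    pop: Population,
    kernel: GaussianMatingKernel,
    config: ScenarioConfig,
    rng: np.random.Generator,
    sexes: Optional[np.ndarray] = None,
) -> Population:
    """Produce the next non-overlapping cohort under the mating kernel.

    For each offspring, with probability 1/2 a uniformly chosen female
    initiates and her mate is drawn from the kernel-weighted conditional
    over all males (symmetric for a male initiator); offspring genomes
    are one maternal plus one paternal gamete, with the X rules described
    in the module docstring. Sexes are an exact half/half permutation
    unless given explicitly.
    """
    if sexes is None:
        codes = _offspring_sex_codes(config.population_size, rng)
    else:
        codes = np.array([0 if s == FEMALE else 1 for s in sexes], dtype=np.int8)
    packed = _step_packed(
        _pack_population(pop), kernel, config.genetic_map, rng, codes
    )
    return _unpack_population(packed, config.genetic_map)


def apply_pulse(
    pop: Population,
    config: ScenarioConfig,
    params: MatingParams,
    kernel: GaussianMatingKernel,
    rng: np.random.Generator,
) -> Population:
    """Form the pulse-generation cohort: resident offspring plus migrants.

    A fraction ``rho = sum_s GFR_s * c_s`` of the new cohort consists of
    unadmixed migrants, ``GFR_s * c_s * N`` per ancestry
    (largest-remainder rounding); the rest are offspring of the previous
    generation. Expected post-pulse composition equals the founding
    proportions ``c`` exactly.
    """
    packed = _pulse_packed(_pack_population(pop), config, params, kernel, rng)
    return _unpack_population(packed, config.genetic_map)


def run_scenario(
    config: ScenarioConfig,
    params: MatingParams,
    rng: np.random.Generator,
) -> SimulationResult:
    """Found the population and iterate all generations.

    Founders are generation 0; under ``two_pulses`` the migrant pulse
    arrives when cohort ``pulse_generation`` is formed. The loop runs on
    the packed-array representation; the final generation is
    materialised as a :class:`Population`.
    """
    kernel = build_kernel(params)
    packed = _pack_population(found_population(config, params, rng))
    history = [packed.mean_proportions()]
    for gen in range(1, config.generations + 1):
        if config.migration_model == "two_pulses" and gen == config.pulse_generation:
            packed = _pulse_packed(packed, config, params, kernel, rng)
        else:
            codes = _offspring_sex_codes(config.population_size, rng)
            packed = _step_packed(packed, kernel, config.genetic_map, rng, codes)
        history.append(packed.mean_proportions())
    return SimulationResult(
        population=_unpack_population(packed, config.genetic_map),
        mean_proportions_by_generation=np.stack(history),
        params=params,
        config=config,
    )
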