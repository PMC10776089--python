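"""Synthetic fixtures and training-set generation.

Everything the pipeline consumes can be produced here without external
downloads: founding-proportion presets for the six admixed American
study populations, toy genetic maps, simulated training sets of
(profile, parameter) pairs, and window-grid local-ancestry call files
emulated from simulated truth (including isolated-window miscalls, the
artefact that inflates the shortest-tract bin).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .forward_simulator import (
    ChromosomeMap,
    GeneticMap,
    Individual,
    ScenarioConfig,
    SimulationResult,
    run_scenario,
)
from .inference import scale_targets, ONE_PULSE_TARGETS, TWO_PULSES_TARGETS
from .local_ancestry_io import AncestryGrid, GridSample
from .mating_model import PriorConfig, sample_mating_params
from .tract_profile import flatten, normalize_profile, population_profile

__all__ = [
    "PopulationPreset",
    "preset_scenarios",
    "get_preset",
    "toy_genetic_map",
    "default_human_map",
    "desk_scale_map",
    "TrainingSet",
    "make_training_set",
    "emulate_local_ancestry_calls",
]


@dataclass(frozen=True)
class PopulationPreset:
    """Founding ancestry proportions of one study population.

    Autosomal mean proportions (AFR, NAT, EUR) are used as founding
    proportions; the simulator's sex-balanced founding reproduces X
    proportions endogenously, so the X means are kept for reference only.
    """

    name: str
    autosomal: tuple[float, float, float]
    x: tuple[float, float, float]

    def founding_proportions(self) -> tuple[float, float, float]:
        p = np.asarray(self.autosomal, dtype=float)
        p = p / p.sum()
        return tuple(float(v) for v in p)


# Mean ancestry percentages (AFR, NAT, EUR) per population; autosomal
# values double as founding proportions after exact renormalisation.
_PRESETS = (
    PopulationPreset("ACB", (88.3, 0.1, 11.8), (94.0, 0.1, 5.4)),
    PopulationPreset("ASW", (76.9, 1.5, 21.7), (77.5, 3.7, 18.3)),
    PopulationPreset("CLM", (8.2, 26.8, 65.1), (8.0, 40.1, 51.5)),
    PopulationPreset("MXL", (4.4, 49.3, 46.5), (5.2, 61.2, 33.2)),
    PopulationPreset("PEL", (3.2, 75.4, 21.6), (5.1, 81.9, 12.5)),
    PopulationPreset("PUR", (13.8, 14.4, 72.0), (15.4, 21.2, 63.0)),
)


def preset_scenarios() -> list[PopulationPreset]:
    """The six bundled population presets (ACB, ASW, CLM, MXL, PEL, PUR)."""
    return list(_PRESETS)


def get_preset(name: str) -> PopulationPreset:
    for p in _PRESETS:
        if p.name == name.upper():
            return p
    raise KeyError(f"unknown preset {name!r}; choose from "
                   f"{[p.name for p in _PRESETS]}")


# Sex-averaged genetic lengths (cM) approximating the human map;
# autosomes total ~3446 cM, X ~180 cM.
_HUMAN_AUTOSOME_CM = (
    286.3, 268.6, 223.4, 214.6, 204.1, 192.0, 187.2, 168.0, 166.4, 181.1,
    158.2, 174.7, 125.9, 120.4, 141.9, 134.0, 128.5, 117.9, 107.9, 108.3,
    62.8, 74.1,
)
_HUMAN_X_CM = 180.9

_DESK_AUTOSOME_CM = (250.0, 200.0, 150.0, 120.0, 100.0)
_DESK_X_CM = 180.0


def toy_genetic_map(
    cm_lengths: Sequence[float],
    include_x: bool = True,
    x_length_cm: float = _DESK_X_CM,
) -> GeneticMap:
    """Uniform-rate chromosomes with the given autosomal cM lengths."""
    chroms = [
        ChromosomeMap(name=f"chr{i + 1}", length_cm=float(L))
        for i, L in enumerate(cm_lengths)
    ]
    if include_x:
        chroms.append(ChromosomeMap(name="chrX", length_cm=float(x_length_cm), is_x=True))
    return GeneticMap(tuple(chroms))


def default_human_map() -> GeneticMap:
    """22 autosomes + X with approximate human genetic lengths."""
    return toy_genetic_map(_HUMAN_AUTOSOME_CM, include_x=True, x_length_cm=_HUMAN_X_CM)


def desk_scale_map() -> GeneticMap:
    """The small default fixture: 5 autosomes (250..100 cM) + X (180 cM)."""
    return toy_genetic_map(_DESK_AUTOSOME_CM, include_x=True, x_length_cm=_DESK_X_CM)


@dataclass
class TrainingSet:
    """Simulated (features, scaled targets) pairs plus a full manifest."""

    features: np.ndarray  # (n, 132) or (n, 126)
    targets: np.ndarray  # (n, 5) or (n, 8), scaled to [0, 1]
    target_names: tuple[str, ...]
    manifest: list[dict]

    def __len__(self):
        return len(self.features)


def _sim_rng(master_seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng([int(master_seed), int(index)])


def make_training_set(
    config: ScenarioConfig,
    prior: PriorConfig,
    n_sims: int,
    seed: int,
    start_index: int = 0,
    normalization: str = "divided_by_total",
    windows: str = "all_windows",
) -> TrainingSet:
    """Simulate ``n_sims`` prior draws and reduce each to a feature vector.

    Simulation ``i`` (global index ``start_index + i``) uses its own RNG
    derived from ``(seed, index)``, so runs are reproducible, resumable
    and can be split across workers: concatenating two half-size runs
    with consecutive index ranges equals one full run.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    with_gfr = config.migration_model == "two_pulses"
    names = TWO_PULSES_TARGETS if with_gfr else ONE_PULSE_TARGETS
    feats, targs, manifest = [], [], []
    for i in range(start_index, start_index + n_sims):
        rng = _sim_rng(seed, i)
        params = sample_mating_params(prior, rng, with_gfr=with_gfr)
        result = run_scenario(config, params, rng)
        profile = population_profile(result.population)
        norm = normalize_profile(profile, mode=normalization, windows=windows)
        feats.append(flatten(norm))
        targs.append(scale_targets(params, names))
        manifest.append(
            {"index": i, "seed": [seed, i], **params.to_dict()}
        )
    return TrainingSet(
        features=np.stack(feats),
        targets=np.stack(targs),
        target_names=names,
        manifest=manifest,
    )


def emulate_local_ancestry_calls(
    sim_result: SimulationResult,
    window_cm: float = 0.1,
    miscall_rate: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    sample_prefix: str = "sim",
) -> AncestryGrid:
    """Discretise true tracts to a call grid, then inject miscalls.

    Each window takes the true ancestry at its midpoint; with
    ``miscall_rate`` each window is then independently flipped to one of
    the two other ancestries, mimicking the isolated-window errors of
    local-ancestry callers that fragment long tracts into short ones.
    """
    if not 0.0 <= miscall_rate < 0.5:
        raise ValueError("miscall_rate must lie in [0, 0.5)")
    rng = np.random.default_rng() if rng is None else rng
    gmap = sim_result.config.genetic_map
    grid = AncestryGrid()
    for idx, ind in enumerate(sim_result.population):
        sample = f"{sample_prefix}{idx:04d}"
        for ci, chrom in enumerate(gmap):
            n_win = int(round(chrom.length_cm / window_cm))
            mids = (np.arange(n_win) + 0.5) * window_cm
            for hap_i, hap in enumerate(ind.haplotypes[ci]):
                calls = hap.ancestries[
                    np.searchsorted(hap.breaks, mids, side="right").clip(
                        0, len(hap.breaks) - 1
                    )
                ].astype(int)
                if miscall_rate > 0:
                    flip = rng.random(n_win) < miscall_rate
                    if flip.any():
                        shift = rng.integers(1, 3, size=int(flip.sum()))
                        calls[flip] = (calls[flip] - 1 + shift) % 3 + 1
                grid.entries.append(
                    GridSample(sample, hap_i, chrom.name, ind.sex, window_cm, calls)
                )
    return grid
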