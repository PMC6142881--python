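"""Synthetic field-trial, glasshouse and sequence data for the pipeline.

Emulates a two-site × five-landrace × two-inoculation × four-replicate
legume inoculation trial: per-plot measurements are drawn as configured
true cell means plus independent Gaussian noise (truncated at zero for
masses), the non-fixing reference species δ¹⁵N values are Gaussian draws
around a per-site mean, and the glasshouse B-value experiment supplies
organ δ¹⁵N and N contents for landraces grown on N-free medium. SSR test
sequences are uniform random backgrounds with exact planted tandem arrays
whose flanks are forced to break the repeat, so a scanner must recover
them at the planted count.

Default magnitudes mirror a West-African Kersting's groundnut trial:
shoot biomass ~15–27 g·plant⁻¹, nodule mass ~3–11 mg·plant⁻¹, shoot %N
~2.8–3.2, legume δ¹⁵N ~1.0–1.8‰ against reference means of +3.95‰ and
+3.04‰ and a B value near −3.8‰.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import fmean

import numpy as np
import pandas as pd

from .ssr import Sequence

__all__ = [
    "TRAITS",
    "TrialSimulationConfig",
    "TrialTables",
    "default_trial_config",
    "generate_trial",
    "generate_ssr_sequences",
]

TRAITS = ("shoot_dm_g", "nodule_dm_mg", "n_pct", "c_pct", "delta15n")

#: Per-(site, landrace) true trait means for the default synthetic trial.
_LANDRACE_MEANS: dict[str, dict[str, dict[str, float]]] = {
    "Nyankpala": {
        "Puffeun": {"shoot_dm_g": 20.40, "nodule_dm_mg": 5.96, "n_pct": 2.77, "c_pct": 39.5, "delta15n": 1.03},
        "Dowie": {"shoot_dm_g": 22.58, "nodule_dm_mg": 7.01, "n_pct": 2.92, "c_pct": 43.2, "delta15n": 1.10},
        "Funsi": {"shoot_dm_g": 27.04, "nodule_dm_mg": 7.36, "n_pct": 2.86, "c_pct": 40.9, "delta15n": 1.07},
        "Sigiri": {"shoot_dm_g": 26.36, "nodule_dm_mg": 5.97, "n_pct": 2.94, "c_pct": 42.5, "delta15n": 1.65},
        "Boli": {"shoot_dm_g": 22.76, "nodule_dm_mg": 8.92, "n_pct": 3.04, "c_pct": 44.7, "delta15n": 1.40},
    },
    "Savelugu": {
        "Puffeun": {"shoot_dm_g": 16.52, "nodule_dm_mg": 4.85, "n_pct": 2.89, "c_pct": 33.8, "delta15n": 1.59},
        "Dowie": {"shoot_dm_g": 16.22, "nodule_dm_mg": 6.28, "n_pct": 3.03, "c_pct": 35.8, "delta15n": 1.64},
        "Funsi": {"shoot_dm_g": 23.13, "nodule_dm_mg": 7.68, "n_pct": 3.22, "c_pct": 36.6, "delta15n": 1.45},
        "Sigiri": {"shoot_dm_g": 14.83, "nodule_dm_mg": 10.77, "n_pct": 2.96, "c_pct": 34.2, "delta15n": 1.81},
        "Boli": {"shoot_dm_g": 17.01, "nodule_dm_mg": 2.85, "n_pct": 3.14, "c_pct": 36.2, "delta15n": 1.82},
    },
}

#: Inoculated-minus-uninoculated additive effect per site and trait.
_INOCULATION_EFFECTS: dict[str, dict[str, float]] = {
    "Nyankpala": {"shoot_dm_g": 3.41, "nodule_dm_mg": -1.80, "n_pct": -0.07, "c_pct": 0.4, "delta15n": -0.06},
    "Savelugu": {"shoot_dm_g": -2.74, "nodule_dm_mg": 3.08, "n_pct": -0.27, "c_pct": -2.2, "delta15n": -0.10},
}

#: Within-cell (plot-to-plot) SDs, sized as ~2× the reported cell SEs (n = 4).
_WITHIN_SD: dict[str, float] = {
    "shoot_dm_g": 2.2,
    "nodule_dm_mg": 1.0,
    "n_pct": 0.24,
    "c_pct": 1.5,
    "delta15n": 0.30,
}

_REFERENCE = {
    "Nyankpala": (3.95, 0.63),
    "Savelugu": (3.04, 0.88),
}

# landrace -> organ -> (true δ¹⁵N ‰, SD, true N content mg, N content SD)
_BVALUE = {
    "Puffeun": {"shoot": (-3.68, 0.10, 120.0, 8.0), "root": (-2.60, 0.10, 40.0, 4.0)},
    "Funsi": {"shoot": (-3.99, 0.10, 130.0, 8.0), "root": (-3.31, 0.10, 45.0, 4.0)},
}

_MASS_TRAITS = ("shoot_dm_g", "nodule_dm_mg", "n_pct", "c_pct")  # truncated at 0


@dataclass(frozen=True)
class TrialSimulationConfig:
    """True parameters of one simulated factorial inoculation trial.

    Cell means are landrace means plus/minus half the site's inoculation
    effect, so the configured marginals match the landrace and inoculation
    summaries they emulate. The same seed always regenerates the identical
    dataset.
    """

    sites: tuple[str, ...]
    landraces: tuple[str, ...]
    inoculations: tuple[str, ...] = ("uninoculated", "inoculated")
    replicates: int = 4
    landrace_means: dict = field(default_factory=lambda: _LANDRACE_MEANS)
    inoculation_effects: dict = field(default_factory=lambda: _INOCULATION_EFFECTS)
    within_sd: dict = field(default_factory=lambda: dict(_WITHIN_SD))
    reference_params: dict = field(default_factory=lambda: dict(_REFERENCE))
    n_reference_species: int = 9
    bvalue_params: dict = field(default_factory=lambda: _BVALUE)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("need at least 2 replicates")
        if any(sd < 0 for sd in self.within_sd.values()):
            raise ValueError("within-cell SDs must be non-negative")

    def cell_mean(self, site: str, landrace: str, inoculation: str, trait: str) -> float:
        base = self.landrace_means[site][landrace][trait]
        effect = self.inoculation_effects[site][trait]
        sign = 0.5 if inoculation == "inoculated" else -0.5
        return base + sign * effect

    @property
    def true_b_value(self) -> float:
        return fmean(p["shoot"][0] for p in self.bvalue_params.values())

    def implied_ndfa(self, site: str, landrace: str, inoculation: str) -> float:
        """%Ndfa implied by the configured true means (the recovery target)."""
        ref = self.reference_params[site][0]
        leg = self.cell_mean(site, landrace, inoculation, "delta15n")
        return 100.0 * (ref - leg) / (ref - self.true_b_value)


@dataclass(frozen=True)
class TrialTables:
    """The three tables the analysis pipeline consumes."""

    samples: pd.DataFrame
    references: pd.DataFrame
    bvalue: pd.DataFrame


def default_trial_config(seed: int = 0, **overrides) -> TrialSimulationConfig:
    """The stock two-site, five-landrace, four-replicate configuration."""
    params = dict(
        sites=("Nyankpala", "Savelugu"),
        landraces=("Puffeun", "Dowie", "Funsi", "Sigiri", "Boli"),
        seed=seed,
    )
    params.update(overrides)
    return TrialSimulationConfig(**params)


def generate_trial(
    config: TrialSimulationConfig, seed: int | None = None
) -> TrialTables:
    """Draw one complete trial: samples, reference plants and B-value tables.

    Every factorial cell receives exactly ``config.replicates`` rows. Each
    measurement is its true cell mean plus independent Gaussian noise;
    non-negative traits (masses, percentages) are truncated at zero. With
    all SDs zero, every value equals its configured mean exactly.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)

    rows = []
    for site in config.sites:
        for landrace in config.landraces:
            for inoc in config.inoculations:
                for rep in range(1, config.replicates + 1):
                    row = {
                        "site": site,
                        "landrace": landrace,
                        "inoculation": inoc,
                        "replicate": rep,
                    }
                    for trait in TRAITS:
                        mu = config.cell_mean(site, landrace, inoc, trait)
                        value = mu + rng.normal(0.0, config.within_sd[trait])
                        if trait in _MASS_TRAITS:
                            value = max(value, 0.0)
                        row[trait] = value
                    rows.append(row)
    samples = pd.DataFrame(rows)

    ref_rows = []
    for site in config.sites:
        mean, sd = config.reference_params[site]
        for i in range(1, config.n_reference_species + 1):
            ref_rows.append(
                {
                    "site": site,
                    "species": f"reference_sp_{i}",
                    "delta15n": mean + rng.normal(0.0, sd),
                }
            )
    references = pd.DataFrame(ref_rows)

    b_rows = []
    for landrace, organs in config.bvalue_params.items():
        for organ, (delta_mu, delta_sd, n_mu, n_sd) in organs.items():
            b_rows.append(
                {
                    "landrace": landrace,
                    "organ": organ,
                    "delta15n": delta_mu + rng.normal(0.0, delta_sd),
                    "n_content_mg": max(n_mu + rng.normal(0.0, n_sd), 0.0),
                }
            )
    bvalue = pd.DataFrame(b_rows)

    return TrialTables(samples=samples, references=references, bvalue=bvalue)


def generate_ssr_sequences(
    n: int,
    length: int,
    planted: list[tuple[str, int, int]] | None = None,
    seed: int = 0,
) -> list[Sequence]:
    """Random sequences with exact planted tandem arrays.

    ``planted`` lists (motif, repeats, start) with 1-based starts; every
    sequence receives the same plants. Arrays must fit inside the sequence
    and must not overlap. The bases flanking each array are forced to
    differ from the repeat's continuation, so the planted run is maximal
    and a correct scanner reports exactly the planted repeat count.
    """
    if length < 1:
        raise ValueError("sequence length must be >= 1")
    if n < 1:
        raise ValueError("need at least one sequence")
    planted = planted or []

    intervals = []
    for motif, repeats, start in planted:
        if not motif or set(motif.upper()) - set("ACGT"):
            raise ValueError(f"motif {motif!r} must be non-empty over ACGT")
        if repeats < 2:
            raise ValueError("a tandem array needs at least 2 repeats")
        end = start + len(motif) * repeats - 1  # 1-based inclusive
        if start < 1 or end > length:
            raise ValueError(f"planted array ({motif},{repeats}) at {start} exceeds length {length}")
        intervals.append((start, end, motif.upper(), repeats))
    intervals.sort()
    for (s1, e1, *_), (s2, _, *_) in zip(intervals, intervals[1:]):
        if s2 <= e1:
            raise ValueError("planted arrays overlap")

    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    records = []
    for i in range(1, n + 1):
        arr = rng.choice(bases, size=length)
        for start, end, motif, repeats in intervals:
            arr[start - 1 : end] = list(motif * repeats)
            # break the repeat at both flanks so the array is non-extendable
            if start >= 2 and arr[start - 2] == motif[-1]:
                arr[start - 2] = rng.choice([b for b in "ACGT" if b != motif[-1]])
            if end < length and arr[end] == motif[0]:
                arr[end] = rng.choice([b for b in "ACGT" if b != motif[0]])
        records.append(Sequence(id=f"seq_{i}", bases="".join(arr)))
    return records
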