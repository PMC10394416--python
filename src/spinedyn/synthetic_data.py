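"""Seeded generators for synthetic spine-size datasets.

Two experimental layouts are emulated so that every downstream stage
(distribution fitting, group statistics, inference) can be exercised
without any external download:

* ``abGC`` — adult-born dentate granule cells: spines sampled per cell in
  three molecular layers (IML, MML, OML), at three cell ages (21, 28,
  35 days post-injection), in two hemispheres (``ipsi`` stimulated,
  ``contra`` control).  Long-term plasticity is emulated as multiplicative
  shifts of the per-condition log-moments: the stimulated MML broadens
  (homosynaptic potentiation) while the ipsilateral IML/OML narrow
  (heterosynaptic depression).
* ``CA1`` — CA1 pyramidal cells in organotypic culture: two groups
  (``dko`` with blocked transmitter release vs ``control``), three culture
  ages (7, 14, 21 days in vitro), and spine types (mushroom / thin /
  stubby / other) drawn with fixed proportions.  Mushroom and thin spines
  are separated by a single head-area cutoff, reproducing the size-based
  classification artefact seen in real typed data.

Head areas are drawn i.i.d. LogNormal(mu_c, sigma_c) per condition.  The
per-condition log-moments are illustrative defaults (the source datasets
do not come with published per-condition values); they are chosen so that
samples are unmistakably right-skewed at realistic per-cell counts.
"""

from __future__ import annotations


from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigurationError, DataValidationError

LAYERS = ("IML", "MML", "OML")
ABGC_AGES = (21, 28, 35)  # days post-injection
CA1_AGES = (7, 14, 21)  # days in vitro
HEMISPHERES = ("ipsi", "contra")
CA1_GROUPS = ("dko", "control")
SPINE_TYPES = ("mushroom", "thin", "stubby", "other")

#: fraction of mushroom / thin / stubby / other spines in CA1 pyramidal cells
CA1_TYPE_PROPORTIONS = (0.2285, 0.2373, 0.5116, 0.0226)

#: cells available per (age, hemisphere) in the abGC layout
ABGC_CELL_COUNTS = {
    (21, "ipsi"): 12,
    (21, "contra"): 9,
    (28, "ipsi"): 18,
    (28, "contra"): 18,
    (35, "ipsi"): 30,
    (35, "contra"): 24,
}
#: animals per abGC cell age
ABGC_ANIMAL_COUNTS = {21: 3, 28: 6, 35: 5}

#: cells per (group, div) in the CA1 layout
CA1_CELL_COUNTS = {
    ("dko", 7): 6,
    ("dko", 14): 7,
    ("dko", 21): 6,
    ("control", 7): 5,
    ("control", 14): 9,
    ("control", 21): 8,
}

TABLE_COLUMNS = (
    "animal_id",
    "cell_id",
    "dataset",
    "layer",
    "age",
    "side_or_group",
    "spine_type",
    "head_area_um2",
)


@dataclass(frozen=True)
class ConditionLabel:
    """One experimental condition: dataset, layer/type stratum, age, side."""

    dataset: str
    layer: str | None
    age: int
    side_or_group: str
    spine_type: str | None = None

    def __post_init__(self) -> None:
        if self.dataset not in ("abGC", "CA1"):
            raise ConfigurationError(f"unknown dataset {self.dataset!r}")
        if self.dataset == "abGC":
            if self.layer not in LAYERS:
                raise ConfigurationError("abGC conditions need a layer in IML/MML/OML")
            if self.spine_type is not None:
                raise ConfigurationError("spine_type applies only to CA1 conditions")
            if self.side_or_group not in HEMISPHERES:
                raise ConfigurationError("abGC side must be 'ipsi' or 'contra'")
        else:
            if self.layer is not None:
                raise ConfigurationError("layer applies only to abGC conditions")
            if self.side_or_group not in CA1_GROUPS:
                raise ConfigurationError("CA1 group must be 'dko' or 'control'")


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic spine-table generator.

    ``mu`` and ``sigma`` are the baseline log-moments of the head area in
    µm².  ``plasticity_effects`` maps a ``(layer, side_or_group)`` key to a
    ``(mu_factor, sigma_factor)`` pair applied multiplicatively to the
    baseline log-moments of that condition.  ``mushroom_thin_cutoff`` of
    ``None`` resolves to the lognormal quantile consistent with the
    configured mushroom/thin proportions, so realized type fractions match
    the configured ones in expectation.
    """

    dataset: str = "abGC"
    mu: float = -1.0
    sigma: float = 0.5
    cells_per_condition: int = 12
    cell_counts: dict | None = None  # (age, side)->n for abGC, (group, div)->n for CA1
    spines_per_cell_range: tuple[int, int] = (60, 105)
    plasticity_effects: dict = field(default_factory=dict)
    type_proportions: tuple[float, float, float, float] = CA1_TYPE_PROPORTIONS
    mushroom_thin_cutoff: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dataset not in ("abGC", "CA1"):
            raise ConfigurationError(f"unknown dataset {self.dataset!r}")
        if not self.sigma > 0:
            raise ConfigurationError("sigma must be strictly positive")
        lo, hi = self.spines_per_cell_range
        if lo < 10 or hi < lo:
            raise ConfigurationError("spines_per_cell_range must satisfy 10 <= min <= max")
        props = np.asarray(self.type_proportions, dtype=float)
        if (props < 0).any() or abs(props.sum() - 1.0) > 1e-9:
            raise ConfigurationError("type_proportions must be >= 0 and sum to 1")
        for key, (fm, fs) in self.plasticity_effects.items():
            if self.sigma * fs <= 0:
                raise ConfigurationError(f"sigma factor for {key} yields non-positive sigma")

    def condition_moments(self, layer_or_group: str, side: str) -> tuple[float, float]:
        """Log-moments (mu_c, sigma_c) of one condition after plasticity shifts."""
        fm, fs = self.plasticity_effects.get((layer_or_group, side), (1.0, 1.0))
        return self.mu * fm, self.sigma * fs

    def resolved_cutoff(self) -> float:
        """Mushroom/thin head-area cutoff in µm².

        Defaults to the baseline lognormal quantile at which the share of
        headed (non-stubby, non-other) spines above the cutoff equals the
        configured mushroom fraction.
        """
        if self.mushroom_thin_cutoff is not None:
            return float(self.mushroom_thin_cutoff)
        p_m, p_t = self.type_proportions[0], self.type_proportions[1]
        q_thin = p_t / (p_m + p_t)
        return float(np.exp(self.mu + self.sigma * norm.ppf(q_thin)))


def default_abgc_config(seed: int = 0) -> GeneratorConfig:
    """abGC layout with plasticity-like shifts on the stimulated hemisphere."""
    effects = {
        ("MML", "ipsi"): (1.0, 1.15),  # homosynaptic potentiation broadens
        ("IML", "ipsi"): (1.0, 0.85),  # heterosynaptic depression narrows
        ("OML", "ipsi"): (1.0, 0.85),
    }
    return GeneratorConfig(
        dataset="abGC",
        cell_counts=dict(ABGC_CELL_COUNTS),
        plasticity_effects=effects,
        seed=seed,
    )


def default_ca1_config(seed: int = 0) -> GeneratorConfig:
    """CA1 layout; no group effect on the log-moments by default."""
    return GeneratorConfig(
        dataset="CA1",
        cell_counts=dict(CA1_CELL_COUNTS),
        spines_per_cell_range=(60, 105),
        seed=seed,
    )


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def assign_spine_types(
    areas: np.ndarray,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Assign a spine type to each head area.

    Stubby and 'other' spines are drawn by proportion independently of
    size.  The remaining (headed) spines are split purely by the area
    cutoff: area >= cutoff -> mushroom, area < cutoff -> thin.
    """
    areas = np.asarray(areas, dtype=float)
    if (areas <= 0).any():
        raise DataValidationError("head areas must be strictly positive")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    p_m, p_t, p_s, p_o = config.type_proportions
    cat = rng.choice(3, size=areas.size, p=(p_m + p_t, p_s, p_o))
    cutoff = config.resolved_cutoff()
    types = np.empty(areas.size, dtype=object)
    headed = cat == 0
    types[headed & (areas >= cutoff)] = "mushroom"
    types[headed & (areas < cutoff)] = "thin"
    types[cat == 1] = "stubby"
    types[cat == 2] = "other"
    return types


def generate_uniform_weights(n: int, lo: float, hi: float, seed: int) -> np.ndarray:
    """``n`` i.i.d. Uniform(lo, hi) draws, deterministic given ``seed``."""
    if not 0 <= lo < hi:
        raise ConfigurationError("require 0 <= lo < hi")
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    return np.random.default_rng(seed).uniform(lo, hi, size=int(n))


def generate_spine_table(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a long-format spine table for the configured layout.

    One row per spine with columns ``animal_id, cell_id, dataset, layer,
    age, side_or_group, spine_type, head_area_um2``.  Deterministic given
    ``config.seed``.
    """
    rng_areas, rng_counts, rng_types = _spawn(config.seed, 3)
    lo, hi = config.spines_per_cell_range
    rows: list[pd.DataFrame] = []

    if config.dataset == "abGC":
        for age in ABGC_AGES:
            n_animals = ABGC_ANIMAL_COUNTS[age]
            for side in HEMISPHERES:
                n_cells = (config.cell_counts or {}).get(
                    (age, side), config.cells_per_condition
                )
                for c in range(n_cells):
                    animal = f"rat{age}dpi_a{c % n_animals}"
                    cell = f"abGC_{age}dpi_{side}_c{c:02d}"
                    for layer in LAYERS:
                        mu_c, sig_c = config.condition_moments(layer, side)
                        n_sp = int(rng_counts.integers(lo, hi + 1))
                        areas = rng_areas.lognormal(mu_c, sig_c, n_sp)
                        rows.append(
                            pd.DataFrame(
                                {
                                    "animal_id": animal,
                                    "cell_id": cell,
                                    "dataset": "abGC",
                                    "layer": layer,
                                    "age": age,
                                    "side_or_group": side,
                                    "spine_type": pd.NA,
                                    "head_area_um2": areas,
                                }
                            )
                        )
    else:
        for group in CA1_GROUPS:
            for div in CA1_AGES:
                n_cells = (config.cell_counts or {}).get(
                    (group, div), config.cells_per_condition
                )
                for c in range(n_cells):
                    animal = f"mouse_{group}_{div}div_a{c}"
                    cell = f"CA1_{group}_{div}div_c{c:02d}"
                    mu_c, sig_c = config.condition_moments(group, div)
                    n_sp = int(rng_counts.integers(lo, hi + 1))
                    areas = rng_areas.lognormal(mu_c, sig_c, n_sp)
                    types = assign_spine_types(areas, config, rng_types)
                    rows.append(
                        pd.DataFrame(
                            {
                                "animal_id": animal,
                                "cell_id": cell,
                                "dataset": "CA1",
                                "layer": pd.NA,
                                "age": div,
                                "side_or_group": group,
                                "spine_type": types,
                                "head_area_um2": areas,
                            }
                        )
                    )

    table = pd.concat(rows, ignore_index=True)
    return table[list(TABLE_COLUMNS)]


def write_spine_table(table: pd.DataFrame, path) -> None:
    """Write a spine table as CSV with the canonical column order."""
    table.to_csv(path, index=False, float_format="%.10g")


def read_spine_table(path) -> pd.DataFrame:
    """Read and validate a spine-table CSV.

    Raises :class:`DataValidationError` naming every missing column or
    contract violation.
    """
    table = pd.read_csv(path)
    problems = [f"missing column: {c}" for c in TABLE_COLUMNS if c not in table.columns]
    if problems:
        raise DataValidationError("; ".join(problems))
    areas = table["head_area_um2"]
    if areas.isna().any() or (areas <= 0).any():
        raise DataValidationError("head_area_um2 must be strictly positive and non-missing")
    return table
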