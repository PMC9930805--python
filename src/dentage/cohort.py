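"""Synthetic cohort generator emulating a stratified cross-sectional design.

Generates a cohort of children aged 6-15 stratified by sex and nine 1-year
age bins (default cell counts reproduce the reference design: 535 subjects,
269 male / 266 female, split 7:3 into 358 training and 177 testing). Each
subject gets seven per-tooth Nolla stages whose sum follows the sex-specific
quadratic score-age curve plus Gaussian noise, a companion Demirjian staging
derived from tooth maturity fractions, and a deterministic per-cell
train/test split.

The generator targets the statistical structure the downstream analysis
assumes (stratification, quadratic mean score, additive noise, lattice
quantisation); it is not a mechanistic model of odontogenesis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calibration import REFERENCE_COEFFICIENTS
from .errors import ConfigurationError, PartitionError
from .staging import DEMIRJIAN_STAGES, FDI_TEETH, snap_to_nolla_lattice

NOLLA_COLUMNS = tuple(f"nolla_{t}" for t in FDI_TEETH)
DEM_COLUMNS = tuple(f"dem_{t}" for t in FDI_TEETH)


@dataclass(frozen=True)
class CohortCell:
    """One design cell: an age bin x sex with train/test counts."""

    age_lower: int
    sex: str
    n_train: int
    n_test: int

    @property
    def label(self) -> str:
        return f"{self.age_lower}.01-{self.age_lower + 1}.00"

    @property
    def n(self) -> int:
        return self.n_train + self.n_test


@dataclass(frozen=True)
class CohortDesign:
    """Age-bin x sex stratification with per-cell train/test counts."""

    cells: tuple[CohortCell, ...]

    def __post_init__(self) -> None:
        if any(c.n_train < 0 or c.n_test < 0 for c in self.cells):
            raise ConfigurationError("cell counts must be non-negative")

    @classmethod
    def default(cls) -> "CohortDesign":
        """The reference design: 20/18/9/8 in the 6.01-7.00 bin, 20/20/10/10
        elsewhere; totals 180+178 train, 89+88 test, 535 overall."""
        cells = []
        for lo in range(6, 15):
            if lo == 6:
                cells.append(CohortCell(lo, "male", 20, 9))
                cells.append(CohortCell(lo, "female", 18, 8))
            else:
                cells.append(CohortCell(lo, "male", 20, 10))
                cells.append(CohortCell(lo, "female", 20, 10))
        return cls(tuple(cells))

    @property
    def n_train(self) -> int:
        return sum(c.n_train for c in self.cells)

    @property
    def n_test(self) -> int:
        return sum(c.n_test for c in self.cells)

    @property
    def n_total(self) -> int:
        return self.n_train + self.n_test


@dataclass(frozen=True)
class GeneratorConfig:
    """All tunables of the synthetic cohort generator.

    ``coefficients`` are the per-sex (a, b, c) of the latent quadratic
    score-age curve, defaulting to the reference calibration.
    ``score_noise_sd`` (score units) is the SD of the additive Gaussian
    noise on the latent Nolla sum. ``tooth_profile`` distributes the sum
    across the seven teeth (non-negative weights summing to 1);
    ``per_tooth_jitter_sd`` adds stage-level heterogeneity before lattice
    snapping.
    """

    design: CohortDesign = field(default_factory=CohortDesign.default)
    coefficients: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(REFERENCE_COEFFICIENTS)
    )
    score_noise_sd: float = 2.5
    tooth_profile: tuple[float, ...] = (1 / 7,) * 7
    per_tooth_jitter_sd: float = 0.25
    seed: int = 0
    snap_stages: bool = True

    def __post_init__(self) -> None:
        if len(self.tooth_profile) != 7 or any(w < 0 for w in self.tooth_profile):
            raise ConfigurationError("tooth_profile needs 7 non-negative weights")
        if not math.isclose(sum(self.tooth_profile), 1.0, abs_tol=1e-9):
            raise ConfigurationError("tooth_profile must sum to 1 within 1e-9")
        if self.score_noise_sd < 0 or self.per_tooth_jitter_sd < 0:
            raise ConfigurationError("noise SDs must be non-negative")

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)


def draw_ages(design: CohortDesign, rng: np.random.Generator) -> pd.DataFrame:
    """Chronological ages for every design cell, discrete-uniform on the
    0.01-year grid within each (lower+0.01, upper] bin."""
    rows = []
    for cell in design.cells:
        cents = rng.integers(cell.age_lower * 100 + 1, (cell.age_lower + 1) * 100 + 1,
                             size=cell.n)
        for ca in cents / 100.0:
            rows.append({"sex": cell.sex, "ca_years": float(ca),
                         "age_group": cell.label})
    return pd.DataFrame(rows)


def latent_sum_score(
    ca: np.ndarray | float,
    sex: str,
    coefficients: dict[str, tuple[float, float, float]],
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Latent Nolla sum: quadratic mean curve + Gaussian noise, clipped to [0, 70]."""
    a, b, c = coefficients[sex]
    ca = np.atleast_1d(np.asarray(ca, dtype=float))
    mean = a + b * ca + c * ca**2
    noisy = mean + rng.normal(0.0, noise_sd, size=ca.shape) if noise_sd > 0 else mean
    return np.clip(noisy, 0.0, 70.0)


def allocate_tooth_stages(
    target_sum: float,
    tooth_profile: tuple[float, ...],
    jitter_sd: float,
    rng: np.random.Generator,
    snap: bool = True,
) -> tuple[float, ...]:
    """Distribute a target Nolla sum over the seven teeth.

    Each tooth's raw value is its profile share of the target plus Gaussian
    jitter, clipped to [0, 10]. With ``snap`` the value is quantised to the
    nearest Nolla lattice point; the snapping residual is carried into the
    next tooth so the realised sum stays within one lattice gap (<= 0.15)
    of the target when jitter is off.
    """
    if not math.isclose(sum(tooth_profile), 1.0, abs_tol=1e-9):
        raise ConfigurationError("tooth_profile must sum to 1")
    if not 0.0 <= target_sum <= 70.0:
        raise ValueError(f"target_sum {target_sum} outside [0, 70]")
    raw = np.array([target_sum * w for w in tooth_profile])
    if jitter_sd > 0:
        raw = raw + rng.normal(0.0, jitter_sd, size=7)
    out = []
    carry = 0.0
    for value in raw:
        value = float(np.clip(value + carry, 0.0, 10.0))
        if snap:
            snapped = snap_to_nolla_lattice(value)
            carry = value - snapped
            out.append(snapped)
        else:
            carry = 0.0
            out.append(value)
    return tuple(out)


def derive_demirjian_stages(nolla_stages: tuple[float, ...]) -> tuple[str, ...]:
    """Companion Demirjian letters from Nolla stages.

    Maturity fraction m = nolla/10 is mapped through eight equal-width bins:
    m = 0 gives no calcification, otherwise stage ceil(8m) of A..H. This is
    a modelling convenience; real stage systems are not affinely related.
    """
    out = []
    for v in nolla_stages:
        m = v / 10.0
        if m <= 0:
            out.append("0")
        else:
            out.append(DEMIRJIAN_STAGES[min(8, math.ceil(8 * m - 1e-12))])
    return tuple(out)


def generate_cohort(
    config: GeneratorConfig | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Full synthetic cohort as one DataFrame, one row per subject.

    Columns: subject_id, sex, ca_years, age_group, nolla_31..37, dem_31..37,
    nolla_sum (realised, post-snapping), nolla_sum_raw (pre-snapping
    diagnostic), latent_score (noise-free curve value).
    """
    config = config or GeneratorConfig()
    rng = rng or np.random.default_rng(config.seed)
    frame = draw_ages(config.design, rng)
    n = len(frame)
    frame.insert(0, "subject_id", [f"S{i + 1:04d}" for i in range(n)])

    latents, targets = np.empty(n), np.empty(n)
    stage_cols = {c: np.empty(n) for c in NOLLA_COLUMNS}
    dem_cols = {c: np.empty(n, dtype=object) for c in DEM_COLUMNS}
    for sex in ("male", "female"):
        mask = (frame["sex"] == sex).to_numpy()
        ca = frame.loc[mask, "ca_years"].to_numpy()
        a, b, c = config.coefficients[sex]
        latents[mask] = a + b * ca + c * ca**2
        targets[mask] = latent_sum_score(
            ca, sex, config.coefficients, config.score_noise_sd, rng
        )
    for i in range(n):
        stages = allocate_tooth_stages(
            targets[i], config.tooth_profile, config.per_tooth_jitter_sd, rng,
            snap=config.snap_stages,
        )
        letters = derive_demirjian_stages(stages)
        for col, v in zip(NOLLA_COLUMNS, stages):
            stage_cols[col][i] = v
        for col, s in zip(DEM_COLUMNS, letters):
            dem_cols[col][i] = s
    for col, vals in stage_cols.items():
        frame[col] = vals
    for col, vals in dem_cols.items():
        frame[col] = vals
    frame["nolla_sum"] = np.round(sum(stage_cols[c] for c in NOLLA_COLUMNS), 10)
    frame["nolla_sum_raw"] = targets
    frame["latent_score"] = latents
    return frame


def split_train_test(
    cohort: pd.DataFrame,
    design: CohortDesign,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell random partition into exactly (n_train, n_test) subjects.

    Deterministic for a fixed seed. Raises :class:`PartitionError` naming
    any cell with fewer subjects than the design requires.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for cell in design.cells:
        mask = (cohort["sex"] == cell.sex) & (cohort["age_group"] == cell.label)
        idx = cohort.index[mask].to_numpy()
        if idx.size < cell.n:
            raise PartitionError(
                f"cell {cell.sex} {cell.label}: {idx.size} subjects < "
                f"required {cell.n_train}+{cell.n_test}"
            )
        perm = rng.permutation(idx)
        train_idx.append(perm[: cell.n_train])
        test_idx.append(perm[cell.n_train : cell.n])
    train = cohort.loc[np.concatenate(train_idx)].sort_index()
    test = cohort.loc[np.concatenate(test_idx)].sort_index()
    return train, test
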