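"""Synthetic endmember spectra and blend designs.

No measured tobacco spectra are distributed with this package, so every
downstream stage is exercised on synthetic data that emulates the study
design: six highly similar pure-variety spectra (same plant species), all
equal-proportion k-subset blends for k = 1..6, trituration series spiking one
variety at low level into an equal quinary background, and the instrumental
effects (multiplicative scatter, additive affine baseline, white noise) the
pre-treatments are meant to remove.

Mixing follows first-order Beer-Lambert behaviour: the clean spectrum of a
blend is the proportion-weighted sum of the endmember spectra, which makes
exact parameter recovery a testable noise-free limit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict

import numpy as np

from .io import DEFAULT_VARIETIES, CompositionTable, SpectraSet, ValidationError

_K_LABELS = {1: "pure", 2: "binary", 3: "ternary", 4: "quaternary",
             5: "quinary", 6: "senary"}

#: trituration spike levels in percent
DEFAULT_TRITURATION_LEVELS = (1.0, 2.0, 5.0, 8.0)


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Independent deterministic stream derived from one user seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


@dataclass(frozen=True)
class GeneratorConfig:
    """Conditions of the synthetic acquisition.

    ``mode`` selects the instrument grid: NIR is 4000-10000 cm^-1 at 8 cm^-1
    resolution, MIDIR is the 650-2000 cm^-1 fingerprint region at 4 cm^-1.
    ``similarity_delta`` scales variety-specific band amplitude relative to
    the shared backbone; small values make the endmembers nearly identical,
    as expected for varieties of the same plant.  The three sigmas control
    per-sample multiplicative scatter (std of the log factor), the additive
    affine baseline (std of offset and slope) and i.i.d. white noise per
    channel (absorbance units).
    """

    seed: int
    mode: str = "NIR"
    n_shared_bands: int = 30
    n_specific_bands: int = 8
    band_width_range: tuple = (20.0, 150.0)
    similarity_delta: float = 0.15
    scatter_sigma: float = 0.05
    baseline_sigma: float = 0.01
    noise_sigma: float = 0.001
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if self.mode not in ("NIR", "MIDIR"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if not 0.0 <= self.similarity_delta <= 1.0:
            raise ValidationError("similarity_delta must lie in [0, 1]")
        for name in ("scatter_sigma", "baseline_sigma", "noise_sigma"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        lo, hi = self.band_width_range
        if not 0 < lo <= hi:
            raise ValidationError("band_width_range must be 0 < lo <= hi")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        int(self.seed)  # seed is mandatory and integral

    def grid(self) -> np.ndarray:
        if self.mode == "NIR":
            return np.arange(4000.0, 10000.0 + 4.0, 8.0)
        return np.arange(650.0, 2000.0 + 2.0, 4.0)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["band_width_range"] = list(self.band_width_range)
        return d


@dataclass(eq=False)
class EndmemberSet:
    """Pure-variety spectra on a common grid."""

    grid: np.ndarray
    spectra: np.ndarray  # (n_varieties, n_channels), absorbance >= 0
    variety_names: tuple
    similarity_delta: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.variety_names = tuple(self.variety_names)
        if self.spectra.shape != (len(self.variety_names), self.grid.size):
            raise ValidationError("endmember matrix shape mismatch")
        if np.any(self.spectra < 0):
            raise ValidationError("endmember absorbance must be non-negative")


@dataclass(eq=False)
class MixtureDesign:
    """A composition table plus a design label per row.

    Labels are ``pure``/``binary``/.../``senary`` for the equal-proportion
    subset design, ``trituration`` for the low-level spike series (all six
    components nonzero) and ``commercial`` for screening-style unknowns.
    """

    composition: CompositionTable
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.labels) != self.composition.n_samples:
            raise ValidationError("one design label required per row")
        for i, lab in enumerate(self.labels):
            nz = int(np.count_nonzero(self.composition.proportions[i]))
            if lab in _K_LABELS.values():
                k = next(k for k, v in _K_LABELS.items() if v == lab)
                if nz != k:
                    raise ValidationError(
                        f"row {self.composition.sample_ids[i]!r} labelled "
                        f"{lab!r} but has {nz} nonzero components"
                    )
            elif lab == "trituration" and nz != 6:
                raise ValidationError(
                    f"trituration row {self.composition.sample_ids[i]!r} "
                    f"must have 6 nonzero components, found {nz}"
                )

    @property
    def n_samples(self) -> int:
        return self.composition.n_samples


def concat_designs(*designs: MixtureDesign) -> MixtureDesign:
    ids, labels = [], []
    mats = []
    varieties = designs[0].composition.varieties
    for d in designs:
        if d.composition.varieties != varieties:
            raise ValidationError("cannot concatenate designs over different varieties")
        ids.extend(d.composition.sample_ids)
        labels.extend(d.labels)
        mats.append(d.composition.proportions)
    return MixtureDesign(
        CompositionTable(ids, varieties, np.vstack(mats)), labels
    )


# ----------------------------------------------------------------------
# endmembers

def _band_sum(grid: np.ndarray, centers, widths, amps) -> np.ndarray:
    z = (grid[None, :] - np.asarray(centers)[:, None]) / np.asarray(widths)[:, None]
    return np.asarray(amps) @ np.exp(-0.5 * z**2)


def generate_endmembers(
    config: GeneratorConfig, variety_names=DEFAULT_VARIETIES
) -> EndmemberSet:
    """Draw pure-variety spectra: shared Gaussian bands plus a small
    variety-specific band set scaled by ``similarity_delta``.

    All endmembers share one backbone, so for the default delta their
    pairwise Pearson correlation exceeds 0.9, mimicking the near-identical
    spectra of varieties of a single plant species.
    """
    rng = _rng(config.seed, 0)
    grid = config.grid()
    lo, hi = grid[0], grid[-1]
    wlo, whi = config.band_width_range

    def draw(n):
        centers = rng.uniform(lo, hi, n)
        widths = rng.uniform(wlo, whi, n)
        amps = rng.uniform(0.1, 1.0, n)
        return _band_sum(grid, centers, widths, amps)

    shared = draw(config.n_shared_bands)
    spectra = np.empty((len(variety_names), grid.size))
    for i in range(len(variety_names)):
        spectra[i] = shared + config.similarity_delta * draw(config.n_specific_bands)
    return EndmemberSet(grid, spectra, tuple(variety_names), config.similarity_delta)


# ----------------------------------------------------------------------
# designs

def build_mixture_design(varieties=DEFAULT_VARIETIES) -> MixtureDesign:
    """All nonempty equal-proportion subsets of the varieties (k = 1..len).

    For six varieties this enumerates 63 rows: 6 pures, 15 binaries, 20
    ternaries, 15 quaternaries, 6 quinaries and 1 senary blend, each present
    component at exactly 100/k percent.  Rows are ordered by subset size and
    then lexicographically by component index, so the design is fully
    deterministic.
    """
    varieties = tuple(varieties)
    m = len(varieties)
    if m < 2:
        raise ValidationError("need at least 2 varieties")
    ids, labels, rows = [], [], []
    for k in range(1, m + 1):
        for combo in itertools.combinations(range(m), k):
            row = np.zeros(m)
            row[list(combo)] = 100.0 / k
            rows.append(row)
            ids.append("+".join(varieties[j] for j in combo))
            labels.append(_K_LABELS.get(k, f"{k}-component"))
    return MixtureDesign(CompositionTable(ids, varieties, np.array(rows)), labels)


def build_trituration_design(
    varieties=DEFAULT_VARIETIES, levels=DEFAULT_TRITURATION_LEVELS
) -> MixtureDesign:
    """Spike series: each variety at level L% with the other five varieties
    sharing the remainder equally at (100-L)/5 percent each.

    Default levels 1, 2, 5 and 8 % give 24 rows for six varieties; these
    probe the classifiers' limits of detection.
    """
    varieties = tuple(varieties)
    m = len(varieties)
    if m < 2:
        raise ValidationError("need at least 2 varieties")
    for lev in levels:
        if not 0.0 < lev < 100.0:
            raise ValidationError(f"trituration level {lev} must lie in (0, 100)")
    ids, labels, rows = [], [], []
    for j, v in enumerate(varieties):
        for lev in sorted(levels):
            row = np.full(m, (100.0 - lev) / (m - 1))
            row[j] = lev
            rows.append(row)
            ids.append(f"trit_{v}_{lev:g}")
            labels.append("trituration")
    return MixtureDesign(CompositionTable(ids, varieties, np.array(rows)), labels)


def build_full_design(
    varieties=DEFAULT_VARIETIES, levels=DEFAULT_TRITURATION_LEVELS
) -> MixtureDesign:
    """Subset design plus trituration series (87 rows for six varieties)."""
    return concat_designs(
        build_mixture_design(varieties), build_trituration_design(varieties, levels)
    )


def build_commercial_design(
    varieties=DEFAULT_VARIETIES, n_samples: int = 5, seed: int = 0
) -> MixtureDesign:
    """Screening-style unknowns with uneven proportions.

    Each sample blends 2-4 varieties with lognormal weights normalised to
    100%, producing the wide, uneven proportion ranges encountered in
    commercial products (components from well below 1% up to tens of
    percent), in contrast with the equal-proportion calibration design.
    """
    rng = _rng(seed, 3)
    varieties = tuple(varieties)
    m = len(varieties)
    ids, labels, rows = [], [], []
    for i in range(n_samples):
        k = int(rng.integers(2, min(4, m) + 1))
        combo = np.sort(rng.choice(m, size=k, replace=False))
        w = np.exp(rng.normal(0.0, 1.2, k))
        row = np.zeros(m)
        row[combo] = 100.0 * w / w.sum()
        rows.append(row)
        ids.append(f"comm_{i + 1}")
        labels.append("commercial")
    return MixtureDesign(CompositionTable(ids, varieties, np.array(rows)), labels)


# ----------------------------------------------------------------------
# synthesis

def synthesize_spectra(
    design: MixtureDesign,
    endmembers: EndmemberSet,
    config: GeneratorConfig,
    stream: int = 1,
) -> tuple[SpectraSet, CompositionTable]:
    """Observe the design through the simulated instrument.

    clean_i = sum_v (p_iv / 100) * endmember_v
    obs_i   = exp(g_i) * clean_i + b0_i + b1_i * nu_scaled + eps_i

    with g_i ~ N(0, scatter_sigma^2) and b0_i, b1_i ~ N(0, baseline_sigma^2)
    per sample, eps ~ N(0, noise_sigma^2) i.i.d. per channel, and nu_scaled
    the grid mapped affinely onto [-1, 1].  Deterministic given the config
    seed; ``stream`` separates independent draws (e.g. calibration vs
    screening sets) under one seed.
    """
    comp = design.composition
    if comp.varieties != endmembers.variety_names:
        raise ValidationError(
            f"design varieties {comp.varieties} do not match endmembers "
            f"{endmembers.variety_names}"
        )
    rng = _rng(config.seed, stream)
    grid = endmembers.grid
    clean = (comp.proportions / 100.0) @ endmembers.spectra
    if config.n_replicates > 1:
        clean = np.repeat(clean, config.n_replicates, axis=0)
        ids = [
            f"{sid}_r{r + 1}"
            for sid in comp.sample_ids
            for r in range(config.n_replicates)
        ]
        props = np.repeat(comp.proportions, config.n_replicates, axis=0)
        comp = CompositionTable(ids, comp.varieties, props)
    n = clean.shape[0]
    span = grid[-1] - grid[0] if grid.size > 1 else 1.0
    nu = 2.0 * (grid - (grid[0] + grid[-1]) / 2.0) / span
    g = rng.normal(0.0, config.scatter_sigma, n)
    b0 = rng.normal(0.0, config.baseline_sigma, n)
    b1 = rng.normal(0.0, config.baseline_sigma, n)
    eps = rng.normal(0.0, config.noise_sigma, clean.shape)
    obs = np.exp(g)[:, None] * clean + b0[:, None] + b1[:, None] * nu[None, :] + eps
    meta = {"seed": config.seed, "mode": config.mode, "stream": stream}
    return SpectraSet(grid, obs, list(comp.sample_ids), meta), comp
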