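"""Synthetic FTIR study generator.

Emulates a microbial lipid-screening experiment: a panel of fungal strains
grown on carbohydrate- and oil-based media, measured by high-throughput FTIR
with technical replication, alongside a GC fatty-acid reference table
(SAT/MUFA/PUFA as % of total fatty acids).

The forward model is deliberately simple and analytically tractable:

* each biological sample has a ground-truth composition (SAT, MUFA, PUFA
  closed to 100 %) plus a total-lipid load;
* the pure spectrum is a sum of Gaussian bands whose amplitudes are linear
  maps of the composition (the olefinic C=CH band tracks unsaturation, the
  ester C=O band tracks total lipid, CH2 stretches track acyl chains);
* each recorded spectrum is ``a + b * pure + baseline + water vapor + noise``
  — exactly the distortion family EMSC is designed to remove.

Technical replicates share a composition and differ only in artifact draws.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .spectra import SpectraSet, default_grid

logger = logging.getLogger(__name__)

COMPONENTS = ("SAT", "MUFA", "PUFA")


@dataclass(frozen=True)
class StudyDesign:
    """Factorial layout of the measurement campaign.

    Defaults mirror a 5-strain x 5-medium screen with 3 runs on different
    days, 2 parallel wells per run and 3 technical FTIR replicates per well:
    5*5*3*2*3 = 450 spectra over 150 biological samples.
    """

    n_strains: int = 5
    n_media: int = 5
    n_runs: int = 3
    n_wells_per_sample_per_run: int = 2
    n_technical_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_strains", "n_media", "n_runs",
                     "n_wells_per_sample_per_run", "n_technical_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def n_samples(self) -> int:
        """Biological samples = strain x medium x run x well combinations."""
        return (self.n_strains * self.n_media * self.n_runs
                * self.n_wells_per_sample_per_run)

    @property
    def n_spectra(self) -> int:
        return self.n_samples * self.n_technical_replicates


@dataclass(frozen=True)
class GroundTruthComposition:
    """True fatty-acid profile (% of total fatty acids) and lipid load."""

    sample_id: str
    SAT: float
    MUFA: float
    PUFA: float
    total_lipid: float = 1.0


@dataclass(frozen=True)
class BandModel:
    """One Gaussian absorption band.

    ``amplitude_rule`` maps a composition to the band amplitude as
    ``const + c_SAT*SAT + c_MUFA*MUFA + c_PUFA*PUFA + c_lipid*total_lipid``
    (keys: ``const``, ``SAT``, ``MUFA``, ``PUFA``, ``total_lipid``).
    """

    center: float
    width: float  # Gaussian sigma, cm^-1
    constituent: str
    amplitude_rule: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be > 0")

    def amplitude(self, comp: GroundTruthComposition) -> float:
        r = self.amplitude_rule
        a = (r.get("const", 0.0)
             + r.get("SAT", 0.0) * comp.SAT
             + r.get("MUFA", 0.0) * comp.MUFA
             + r.get("PUFA", 0.0) * comp.PUFA
             + r.get("total_lipid", 0.0) * comp.total_lipid)
        if a < 0:
            raise ValueError(
                f"negative amplitude for {self.constituent} band at "
                f"{self.center} cm^-1 (composition {comp.sample_id})")
        return a


def default_bands(olefinic_center: float = 3008.0) -> list[BandModel]:
    """Band set of the forward model (amplitudes in absorbance units).

    The olefinic C=CH stretch responds only to unsaturated fatty acids,
    the ester C=O band only to total lipid load; CH2/CH3 stretches carry
    the acyl-chain signal; amide and carbohydrate bands are the non-lipid
    cell background.
    """
    return [
        BandModel(olefinic_center, 6.0, "CH=CH olefinic",
                  {"MUFA": 0.0015, "PUFA": 0.0035}),
        BandModel(2960.0, 8.0, "CH3 asym stretch", {"const": 0.12}),
        BandModel(2925.0, 9.0, "CH2 asym stretch",
                  {"const": 0.05, "SAT": 0.004, "MUFA": 0.0015}),
        BandModel(2855.0, 8.0, "CH2 sym stretch",
                  {"const": 0.03, "SAT": 0.002, "MUFA": 0.00075}),
        BandModel(1740.0, 10.0, "C=O ester", {"total_lipid": 0.28}),
        BandModel(1655.0, 14.0, "protein amide I", {"const": 0.45}),
        BandModel(1545.0, 12.0, "protein amide II", {"const": 0.28}),
        BandModel(1045.0, 30.0, "carbohydrate fingerprint", {"const": 0.35}),
    ]


# Rotational water-vapor lines (cm^-1) with fixed relative strengths; two
# lines fall inside the 1847-1837 cm^-1 QC window so the water-vapor
# statistic has signal to measure.
WATER_VAPOR_LINES = np.array([
    1889.0, 1870.0, 1846.0, 1840.0, 1794.0, 1772.0, 1718.0, 1670.0,
    1617.0, 1560.0, 1508.0, 1457.0, 1419.0, 1396.0, 1340.0])
WATER_VAPOR_STRENGTHS = np.array([
    0.7, 0.9, 1.0, 0.8, 0.9, 0.6, 0.7, 0.5,
    0.8, 0.6, 0.9, 0.7, 0.5, 0.8, 0.6])
WATER_VAPOR_SIGMA = 1.2


@dataclass(frozen=True)
class ArtifactModel:
    """Per-spectrum measurement distortions.

    The recorded spectrum is
    ``a + b*pure + c1*P1(u) + c2*P2(u) + vapor + noise`` with u the
    wavenumber mapped to [-1, 1] and P_k Legendre polynomials — the additive
    offset ``a``, multiplicative scatter ``b`` and polynomial baseline of
    the EMSC model, plus a water-vapor comb and iid Gaussian noise.

    Defaults are chosen so that generated spectra pass the quality test the
    way accepted instrument spectra do (noise under 1.5e-5 absorbance,
    water-vapor statistic under 3e-4) while leaving EMSC real distortions
    to remove.
    """

    multiplicative_scale_range: tuple[float, float] = (0.9, 1.1)
    additive_offset_range: tuple[float, float] = (-0.02, 0.02)
    baseline_linear_range: tuple[float, float] = (-2e-3, 2e-3)
    baseline_quadratic_range: tuple[float, float] = (-2e-3, 2e-3)
    noise_sd: float = 8e-6
    water_vapor_amplitude_range: tuple[float, float] = (0.0, 1.2e-4)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.multiplicative_scale_range[0] <= 0:
            raise ValueError("multiplicative scale must be strictly positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @classmethod
    def none(cls) -> "ArtifactModel":
        """Identity artifacts: a=0, b=1, no baseline, no vapor, no noise."""
        return cls(multiplicative_scale_range=(1.0, 1.0),
                   additive_offset_range=(0.0, 0.0),
                   baseline_linear_range=(0.0, 0.0),
                   baseline_quadratic_range=(0.0, 0.0),
                   noise_sd=0.0,
                   water_vapor_amplitude_range=(0.0, 0.0))


# ---------------------------------------------------------------------------
# Composition generation
# ---------------------------------------------------------------------------

# Per-strain deviations (dSAT, dMUFA, dPUFA sum to zero; lipid-load offset).
DEFAULT_STRAIN_EFFECTS = {
    "strain_1": ((0.0, 0.0, 0.0), 0.0),
    "strain_2": ((3.0, -2.0, -1.0), 0.1),
    "strain_3": ((-3.0, 2.0, 1.0), -0.1),
    "strain_4": ((2.0, 2.0, -4.0), 0.2),
    "strain_5": ((-2.0, -2.0, 4.0), -0.05),
}

# Carbohydrate media push toward PUFA, oil media toward MUFA (olive being
# the most saturated oil); oil media raise the lipid load.
DEFAULT_MEDIUM_EFFECTS = {
    "glucose": ((0.0, -8.0, 8.0), 0.0),
    "sucrose": ((0.0, -6.0, 6.0), 0.1),
    "canola_oil": ((-5.0, 12.0, -7.0), 0.6),
    "olive_oil": ((5.0, 8.0, -13.0), 0.7),
    "sunflower_oil": ((-3.0, 10.0, -7.0), 0.6),
}

MEDIUM_CLASS = {"glucose": "carbohydrate", "sucrose": "carbohydrate",
                "canola_oil": "oil", "olive_oil": "oil",
                "sunflower_oil": "oil"}

BASE_COMPOSITION = (30.0, 40.0, 30.0)
BASE_TOTAL_LIPID = 1.0


def _effect_names(effects: dict, n: int, kind: str) -> list[str]:
    names = list(effects)
    if len(names) < n:
        names += [f"{kind}_{i + 1}" for i in range(len(names), n)]
    return names[:n]


def generate_compositions(design: StudyDesign,
                          strain_effects: dict | None = None,
                          medium_effects: dict | None = None,
                          biological_noise_sd: float = 2.0,
                          lipid_noise_sd: float = 0.05,
                          base: tuple[float, float, float] = BASE_COMPOSITION,
                          base_lipid: float = BASE_TOTAL_LIPID,
                          rng: np.random.Generator | None = None
                          ) -> pd.DataFrame:
    """Ground-truth compositions, one row per (strain, medium, run, well).

    Composition = base + strain effect + medium effect + iid biological
    noise, then re-closed to sum to 100.  Technical replicates are not
    represented here: they share the composition of their sample.

    Raises ``ValueError`` naming the offending sample if any component
    leaves [0, 100].
    """
    if strain_effects is None:
        strain_effects = DEFAULT_STRAIN_EFFECTS
    if medium_effects is None:
        medium_effects = DEFAULT_MEDIUM_EFFECTS
    if rng is None:
        rng = np.random.default_rng(design.seed)
    strains = _effect_names(strain_effects, design.n_strains, "strain")
    media = _effect_names(medium_effects, design.n_media, "medium")
    zero = ((0.0, 0.0, 0.0), 0.0)
    rows = []
    for si, strain in enumerate(strains):
        s_eff, s_lip = strain_effects.get(strain, zero)
        for mi, medium in enumerate(media):
            m_eff, m_lip = medium_effects.get(medium, zero)
            for run in range(1, design.n_runs + 1):
                for well in range(1, design.n_wells_per_sample_per_run + 1):
                    comp = (np.array(base) + np.array(s_eff)
                            + np.array(m_eff))
                    comp = comp + rng.normal(0.0, biological_noise_sd, 3)
                    total = comp.sum()
                    if total <= 0:
                        raise ValueError(
                            f"degenerate composition for sample "
                            f"s{si+1}m{mi+1}_r{run}_w{well}")
                    comp = comp * (100.0 / total)
                    lipid = (base_lipid + s_lip + m_lip
                             + rng.normal(0.0, lipid_noise_sd))
                    sample_id = f"s{si+1}m{mi+1}_r{run}_w{well}"
                    if np.any(comp < 0) or np.any(comp > 100) or lipid <= 0:
                        raise ValueError(
                            f"composition out of range for sample "
                            f"{sample_id}: SAT={comp[0]:.2f} "
                            f"MUFA={comp[1]:.2f} PUFA={comp[2]:.2f} "
                            f"total_lipid={lipid:.3f}")
                    rows.append({
                        "sample_id": sample_id, "strain": strain,
                        "medium": medium,
                        "medium_class": MEDIUM_CLASS.get(medium, "other"),
                        "run": run, "well": well,
                        "SAT": comp[0], "MUFA": comp[1], "PUFA": comp[2],
                        "total_lipid": lipid,
                    })
    return pd.DataFrame(rows)


def composition_from_row(row) -> GroundTruthComposition:
    return GroundTruthComposition(
        sample_id=str(row["sample_id"]), SAT=float(row["SAT"]),
        MUFA=float(row["MUFA"]), PUFA=float(row["PUFA"]),
        total_lipid=float(row.get("total_lipid", 1.0)))


# ---------------------------------------------------------------------------
# Spectrum rendering
# ---------------------------------------------------------------------------

def pure_spectrum(comp: GroundTruthComposition, bands: list[BandModel],
                  grid: np.ndarray) -> np.ndarray:
    """Artifact-free mixture spectrum: sum of Gaussian bands on ``grid``."""
    if len(bands) == 0:
        raise ValueError("band list is empty")
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty wavenumber grid")
    lo, hi = grid.min(), grid.max()
    out = np.zeros_like(grid)
    for band in bands:
        if not (lo <= band.center <= hi):
            warnings.warn(
                f"band {band.constituent!r} at {band.center} cm^-1 outside "
                f"grid range {hi:g}-{lo:g}; skipped", stacklevel=2)
            continue
        a = band.amplitude(comp)
        out += a * np.exp(-0.5 * ((grid - band.center) / band.width) ** 2)
    return out


def _water_vapor_comb(grid: np.ndarray, amplitude: float) -> np.ndarray:
    out = np.zeros_like(grid)
    for center, strength in zip(WATER_VAPOR_LINES, WATER_VAPOR_STRENGTHS):
        out += (amplitude * strength
                * np.exp(-0.5 * ((grid - center) / WATER_VAPOR_SIGMA) ** 2))
    return out


def render_spectrum(comp: GroundTruthComposition, bands: list[BandModel],
                    artifacts: ArtifactModel, grid: np.ndarray,
                    rng: np.random.Generator | None = None,
                    metadata: dict | None = None):
    """One recorded spectrum: distorted pure mixture on ``grid``.

    With identity artifacts the output equals the pure mixture exactly.
    Passing no ``rng`` derives one from ``artifacts.seed`` (deterministic).
    """
    from .spectra import Spectrum

    if rng is None:
        rng = np.random.default_rng(artifacts.seed)
    grid = np.asarray(grid, dtype=float)
    pure = pure_spectrum(comp, bands, grid)
    b = rng.uniform(*artifacts.multiplicative_scale_range)
    a = rng.uniform(*artifacts.additive_offset_range)
    c1 = rng.uniform(*artifacts.baseline_linear_range)
    c2 = rng.uniform(*artifacts.baseline_quadratic_range)
    vap = rng.uniform(*artifacts.water_vapor_amplitude_range)
    u = (2.0 * (grid - grid.min()) / (grid.max() - grid.min())) - 1.0
    trace = a + b * pure + c1 * u + c2 * (1.5 * u ** 2 - 0.5)
    trace = trace + _water_vapor_comb(grid, vap)
    if artifacts.noise_sd > 0:
        trace = trace + rng.normal(0.0, artifacts.noise_sd, grid.size)
    md = {"sample_id": comp.sample_id}
    if metadata:
        md.update(metadata)
    return Spectrum(grid, trace, md)


# ---------------------------------------------------------------------------
# Full study
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStudy:
    """Output bundle: spectra, GC reference table and ground truth."""

    spectra: SpectraSet
    reference: pd.DataFrame
    ground_truth: pd.DataFrame


def generate_study(design: StudyDesign = StudyDesign(),
                   bands: list[BandModel] | None = None,
                   artifacts: ArtifactModel | None = None,
                   grid: np.ndarray | None = None,
                   gc_noise_sd: float = 1.0,
                   gc_run_bias: dict[int, tuple[float, float, float]] | None = None,
                   **composition_kwargs) -> SyntheticStudy:
    """Generate the full synthetic study.

    Returns one spectrum per (strain, medium, run, well, replicate) and one
    GC reference row per (strain, medium, run, well).  The reference values
    are the ground-truth compositions perturbed by iid GC measurement noise
    (sd ``gc_noise_sd`` %) and an optional per-run bias (dSAT, dMUFA, dPUFA
    added to every sample of that run) emulating day-to-day GC drift.
    """
    if bands is None:
        bands = default_bands()
    if artifacts is None:
        artifacts = ArtifactModel(seed=design.seed)
    if grid is None:
        grid = default_grid()
    ss = np.random.SeedSequence(design.seed)
    comp_seed, artifact_seed, gc_seed = ss.spawn(3)
    truth = generate_compositions(
        design, rng=np.random.default_rng(comp_seed), **composition_kwargs)

    art_rng = np.random.default_rng(artifact_seed)
    spectra = []
    for _, row in truth.iterrows():
        comp = composition_from_row(row)
        for rep in range(1, design.n_technical_replicates + 1):
            md = {"spectrum_id": f"{row['sample_id']}_t{rep}",
                  "sample_id": row["sample_id"],
                  "strain": row["strain"], "medium": row["medium"],
                  "medium_class": row["medium_class"],
                  "run": int(row["run"]), "well": int(row["well"]),
                  "replicate": rep}
            spectra.append(render_spectrum(comp, bands, artifacts, grid,
                                           rng=art_rng, metadata=md))
    spectra_set = SpectraSet.from_spectra(spectra)

    gc_rng = np.random.default_rng(gc_seed)
    reference = truth.copy()
    vals = reference[list(COMPONENTS)].to_numpy(float)
    if gc_run_bias:
        for run, bias in gc_run_bias.items():
            vals[reference["run"].to_numpy() == run] += np.asarray(bias)
    if gc_noise_sd > 0:
        vals = vals + gc_rng.normal(0.0, gc_noise_sd, vals.shape)
    reference[list(COMPONENTS)] = vals
    reference = reference.drop(columns=["total_lipid"])
    return SyntheticStudy(spectra_set, reference, truth)
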