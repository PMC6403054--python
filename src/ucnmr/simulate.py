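"""Synthetic plasma CPMG cohort generator.

Generates cohorts of one-dimensional plasma spectra (optionally as FIDs) with
a configurable two-class effect structure, plus a clinical metadata table
with the same schema the analysis modules consume (endoscopic, histological
and clinical activity scores, routine bloods, medication flags,
demographics).  The simulator is a rendering model, not a physics model: each
resonance is a Lorentzian multiplet whose integral equals
concentration × proton weight, with per-resonance chemical-shift jitter, a
per-sample global shift, a smooth low-order baseline drift and additive
Gaussian noise.  Pulse-sequence physics (relaxation during the echo train,
J-modulation, water presaturation) is deliberately out of scope.

Every output is a pure function of the specification dataclasses and the
random generator passed in, so downstream statistics are reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .processing import FID, Spectrum
from .signatures import (
    EffectTable,
    MetaboliteSignature,
    default_baseline_concentrations,
    default_metabolite_library,
    library_index,
)

__all__ = [
    "CohortSpec",
    "AcquisitionSpec",
    "sample_concentrations",
    "render_spectrum",
    "spectrum_to_fid",
    "simulate_cohort",
    "simulate_longitudinal_study",
    "METADATA_COLUMNS",
]


@dataclass(frozen=True)
class AcquisitionSpec:
    """Spectral window and digitization of the simulated acquisition."""

    ppm_min: float = 0.0
    ppm_max: float = 9.0
    n_points: int = 8192
    observe_frequency: float = 700.0  # MHz

    def __post_init__(self) -> None:
        n = self.n_points
        if n < 4096 or (n & (n - 1)) != 0:
            raise ValueError("n_points must be a power of two >= 4096")
        if self.ppm_max <= self.ppm_min:
            raise ValueError("empty spectral window")

    def axis(self) -> np.ndarray:
        """Ascending ppm axis (FFT-compatible: excludes the right endpoint)."""
        step = (self.ppm_max - self.ppm_min) / self.n_points
        return self.ppm_min + step * np.arange(self.n_points)


@dataclass
class CohortSpec:
    """Study conditions for one simulated two-class cohort.

    Defaults follow the cohort the analysis is designed around: 24 control
    ("low") and 16 case ("high") subjects, 15% between-subject biological
    variation, and noise/jitter/drift levels small relative to the rendered
    peaks (peak heights are of order 10³ intensity units).
    """

    n_per_class: dict[str, int] = field(default_factory=lambda: {"low": 24, "high": 16})
    baseline_concentration: dict[str, float] = field(
        default_factory=default_baseline_concentrations
    )
    between_subject_cv: float = 0.15
    noise_sd: float = 5.0
    shift_jitter_sd: float = 0.002  # ppm, per resonance per sample
    global_shift_sd: float = 0.003  # ppm, per sample (corrected by referencing)
    baseline_drift_amplitude: float = 20.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.n_per_class.values()):
            raise ValueError("need at least 2 subjects per class")
        if not 0.0 <= self.between_subject_cv < 1.0:
            raise ValueError("between_subject_cv must be in [0, 1)")
        if self.noise_sd < 0 or self.shift_jitter_sd < 0:
            raise ValueError("noise_sd and shift_jitter_sd must be >= 0")


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative log-normal factors with mean 1 and coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def sample_concentrations(
    cohort: CohortSpec,
    effects: EffectTable,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw per-subject metabolite concentrations for a two-class cohort.

    The case class (``effects.case_class``) has expected concentration
    ``baseline × (1 + percent_change/100)`` for each affected metabolite;
    subject-level variation is multiplicative log-normal with CV equal to
    ``cohort.between_subject_cv``, so class means are preserved exactly in
    expectation.
    """
    rng = rng if rng is not None else np.random.default_rng(cohort.master_seed)
    unknown = sorted(set(effects.entries) - set(cohort.baseline_concentration))
    if unknown:
        raise ValueError(f"effect table names metabolites without a baseline: {unknown}")
    metabolites = list(cohort.baseline_concentration)
    labels = np.concatenate(
        [np.repeat(cls, n) for cls, n in cohort.n_per_class.items()]
    )
    base = np.array([cohort.baseline_concentration[m] for m in metabolites])
    mult = np.array(
        [effects.multiplier(m) for m in metabolites]
    )
    rows = []
    for cls in labels:
        mean = base * (mult if cls == effects.case_class else 1.0)
        rows.append(mean)
    means = np.vstack(rows)
    factors = _lognormal_factors(rng, cohort.between_subject_cv, means.shape)
    conc = pd.DataFrame(means * factors, columns=metabolites)
    return conc, labels


def render_spectrum(
    concentrations: dict[str, float] | pd.Series,
    library: list[MetaboliteSignature] | None = None,
    acq: AcquisitionSpec = AcquisitionSpec(),
    rng: np.random.Generator | None = None,
    jitter_sd: float = 0.0,
    noise_sd: float = 0.0,
    drift_amplitude: float = 0.0,
    global_shift_sd: float = 0.0,
) -> Spectrum:
    """Render one spectrum as a sum of Lorentzian multiplets plus drift and noise.

    Each line contributes ``concentration × proton_weight × pattern`` of
    integrated area.  Resonances whose lines fall outside the spectral window
    trigger a warning and are truncated to whatever tail the axis covers.
    """
    library = library if library is not None else default_metabolite_library()
    index = library_index(library)
    if rng is None and (jitter_sd > 0 or noise_sd > 0 or drift_amplitude > 0 or global_shift_sd > 0):
        raise ValueError("an rng is required when jitter, noise or drift is enabled")
    x = acq.axis()
    y = np.zeros_like(x)
    global_shift = float(rng.normal(0.0, global_shift_sd)) if global_shift_sd > 0 else 0.0
    for name, conc in dict(concentrations).items():
        if conc < 0:
            raise ValueError(f"negative concentration for {name!r}")
        if conc == 0:
            continue
        if name not in index:
            raise ValueError(f"unknown metabolite {name!r}")
        for res in index[name].resonances:
            shift = global_shift
            if jitter_sd > 0:
                shift += float(rng.normal(0.0, jitter_sd))
            positions = res.line_positions(shift)
            if positions.min() < acq.ppm_min or positions.max() > acq.ppm_max:
                warnings.warn(
                    f"resonance of {name!r} at {res.center + shift:.3f} ppm extends "
                    "outside the spectral window; truncating",
                    stacklevel=2,
                )
            hwhm = res.linewidth / (2.0 * acq.observe_frequency)  # ppm
            areas = conc * res.proton_weight * np.asarray(res.pattern)
            for pos, area in zip(positions, areas):
                y += area * (hwhm / np.pi) / ((x - pos) ** 2 + hwhm**2)
    if drift_amplitude > 0:
        coef = rng.uniform(-1.0, 1.0, size=4)
        xn = np.linspace(-1.0, 1.0, x.size)
        y += drift_amplitude * np.polynomial.polynomial.polyval(xn, coef)
    if noise_sd > 0:
        y += rng.normal(0.0, noise_sd, size=x.size)
    return Spectrum(ppm=x, intensities=y)


def spectrum_to_fid(spectrum: Spectrum, acq: AcquisitionSpec = AcquisitionSpec()) -> FID:
    """Inverse Fourier transform a spectrum into a complex time-domain FID.

    A real absorption spectrum corresponds to a *causal* decaying signal, so
    the two-sided inverse FFT is projected onto non-negative time (the
    discrete analytic-signal construction): the real part of the Fourier
    transform of the result equals the input spectrum exactly, which makes
    ``process_fid(spectrum_to_fid(s))`` with zero line broadening an identity
    on the original grid points, and makes zero-filling well defined.
    """
    x_asc, y_asc = spectrum.ascending()
    n = x_asc.size
    dppm = x_asc[1] - x_asc[0]
    df = dppm * acq.observe_frequency  # Hz per point
    dwell = 1.0 / (n * df)
    two_sided = np.fft.ifft(np.fft.ifftshift(y_asc.astype(complex)))
    causal = np.zeros(n)
    causal[0] = 1.0
    causal[1: n // 2] = 2.0
    causal[n // 2] = 1.0
    fid_points = two_sided * causal
    reference_offset = float(x_asc[n // 2])
    return FID(
        points=fid_points,
        dwell_time=dwell,
        observe_frequency=acq.observe_frequency,
        reference_offset=reference_offset,
    )


# ---------------------------------------------------------------------------
# Metadata generation
# ---------------------------------------------------------------------------

METADATA_COLUMNS = [
    "sample_id", "subject_id", "timepoint", "class_label",
    "uceis", "nancy", "sccai",
    "hb", "wcc", "plt", "alb", "crp", "ferritin", "transferrin_sat",
    "med_topical_5asa", "med_topical_steroid", "med_oral_5asa",
    "med_oral_steroid", "med_immunosuppressant", "med_biologic",
    "age", "sex", "bmi", "extent", "smoking",
]

# Reference-range means/SDs for the routine bloods; deliberately drawn
# independently of class so the independence screens have true-null structure.
_BLOOD_PARAMS = {
    "hb": (140.0, 15.0),
    "wcc": (7.0, 2.0),
    "plt": (280.0, 60.0),
    "alb": (42.0, 4.0),
    "crp": (5.0, 4.0),
    "ferritin": (80.0, 40.0),
    "transferrin_sat": (25.0, 8.0),
}

_MED_PREVALENCE = {
    "med_topical_5asa": 0.35,
    "med_topical_steroid": 0.08,
    "med_oral_5asa": 0.65,
    "med_oral_steroid": 0.18,
    "med_immunosuppressant": 0.25,
    "med_biologic": 0.25,
}


def _draw_bloods(rng: np.random.Generator) -> dict[str, float]:
    out = {}
    for key, (mu, sd) in _BLOOD_PARAMS.items():
        out[key] = float(max(0.0, rng.normal(mu, sd)))
    return out


def _draw_demographics(rng: np.random.Generator) -> dict[str, object]:
    return {
        "age": int(rng.integers(17, 63)),
        "sex": "F" if rng.random() < 0.58 else "M",
        "bmi": float(np.round(rng.normal(25.0, 4.0), 1)),
        "extent": str(rng.choice(["proctitis", "left-sided", "extensive"], p=[0.2, 0.4, 0.4])),
        "smoking": str(rng.choice(["never", "ex", "current"], p=[0.55, 0.40, 0.05])),
    }


def _draw_meds(rng: np.random.Generator) -> dict[str, int]:
    return {k: int(rng.random() < p) for k, p in _MED_PREVALENCE.items()}


def _uceis_for_class(rng: np.random.Generator, cls: str) -> int:
    # low: UCEIS <= 3, high: UCEIS > 3
    return int(rng.integers(0, 4)) if cls == "low" else int(rng.integers(4, 9))


def _nancy_for_class(rng: np.random.Generator, cls: str) -> int:
    # histology tracks endoscopy imperfectly: ~25% land in the excluded
    # grade 2 and a further ~10-15% cross to the discordant side
    if cls == "high":
        return int(rng.choice([3, 4, 2, 1], p=[0.40, 0.25, 0.25, 0.10]))
    return int(rng.choice([0, 1, 2, 3], p=[0.40, 0.25, 0.25, 0.10]))


def simulate_cohort(
    cohort: CohortSpec,
    effects: EffectTable,
    contrast_name: str | None = None,
    acq: AcquisitionSpec = AcquisitionSpec(),
    rng: np.random.Generator | None = None,
    return_fids: bool = False,
    library: list[MetaboliteSignature] | None = None,
) -> tuple[list, pd.DataFrame]:
    """Simulate one spectrum (or FID) per subject plus a metadata table.

    Class labels are generated first; clinical scores are then drawn
    consistently with the labels (a "low"/"high" contrast draws UCEIS ≤ 3 or
    > 3 and a class-consistent Nancy grade; SCCAI and the blood parameters
    are always label-independent noise).
    """
    rng = rng if rng is not None else np.random.default_rng(cohort.master_seed)
    library = library if library is not None else default_metabolite_library()
    effects.validate_against(library)
    conc, labels = sample_concentrations(cohort, effects, rng)
    spectra: list = []
    rows = []
    classes = set(cohort.n_per_class)
    for i, cls in enumerate(labels):
        spectrum = render_spectrum(
            conc.iloc[i],
            library=library,
            acq=acq,
            rng=rng,
            jitter_sd=cohort.shift_jitter_sd,
            noise_sd=cohort.noise_sd,
            drift_amplitude=cohort.baseline_drift_amplitude,
            global_shift_sd=cohort.global_shift_sd,
        )
        spectra.append(spectrum_to_fid(spectrum, acq) if return_fids else spectrum)
        row: dict[str, object] = {
            "sample_id": f"S{i + 1:03d}",
            "subject_id": f"P{i + 1:03d}",
            "timepoint": "baseline",
            "class_label": cls,
        }
        if classes == {"low", "high"}:
            row["uceis"] = _uceis_for_class(rng, cls)
            row["nancy"] = _nancy_for_class(rng, cls)
        else:
            row["uceis"] = int(rng.integers(0, 9))
            row["nancy"] = int(rng.integers(0, 5))
        row["sccai"] = int(rng.integers(0, 11))
        row.update(_draw_bloods(rng))
        row.update(_draw_meds(rng))
        row.update(_draw_demographics(rng))
        rows.append(row)
    metadata = pd.DataFrame(rows, columns=METADATA_COLUMNS)
    if contrast_name is not None:
        metadata.attrs["contrast_name"] = contrast_name
    return spectra, metadata


def simulate_longitudinal_study(
    n_improved: int = 18,
    n_worsened: int = 15,
    n_nochange: int = 7,
    n_low: int = 24,
    n_high: int = 16,
    cohort: CohortSpec | None = None,
    acq: AcquisitionSpec = AcquisitionSpec(),
    rng: np.random.Generator | None = None,
    return_fids: bool = False,
    library: list[MetaboliteSignature] | None = None,
) -> tuple[list, pd.DataFrame]:
    """Simulate the full prospective study: 40 subjects × 2 timepoints.

    Each subject gets a baseline endoscopic class (low/high UCEIS, default
    24/16), an outcome (improved / worsened / no change, default 18/15/7) and
    a followup UCEIS implied by the outcome.  Concentrations compose three
    multiplicative pieces: a per-subject log-normal biological factor shared
    across timepoints, the endoscopic-activity effect table applied according
    to each sample's own UCEIS class, and the prognostic effect table applied
    to baseline samples according to the outcome (no-change subjects get the
    square root of the prognostic multiplier, placing them midway between the
    classes in log space).  Nancy grades track the UCEIS class imperfectly;
    SCCAI, bloods and medications are label-independent noise.
    """
    from .signatures import default_effect_tables

    cohort = cohort if cohort is not None else CohortSpec()
    rng = rng if rng is not None else np.random.default_rng(cohort.master_seed)
    library = library if library is not None else default_metabolite_library()
    tables = default_effect_tables()
    uceis_eff = tables["uceis_high_vs_low"]
    prog_eff = tables["worsening_vs_improving"]

    n_subjects = n_low + n_high
    if n_improved + n_worsened + n_nochange != n_subjects:
        raise ValueError("outcome counts must sum to the number of subjects")

    base_class = np.array(["low"] * n_low + ["high"] * n_high)
    rng.shuffle(base_class)
    outcome = np.array(
        ["improved"] * n_improved + ["worsened"] * n_worsened + ["nochange"] * n_nochange
    )
    rng.shuffle(outcome)

    metabolites = list(cohort.baseline_concentration)
    base = np.array([cohort.baseline_concentration[m] for m in metabolites])
    uceis_mult = np.array([uceis_eff.multiplier(m) for m in metabolites])
    prog_mult = np.array([prog_eff.multiplier(m) for m in metabolites])

    spectra: list = []
    rows = []
    sample_counter = 0
    for i in range(n_subjects):
        subj = f"P{i + 1:03d}"
        subject_factor = _lognormal_factors(rng, cohort.between_subject_cv, len(metabolites))
        demo = _draw_demographics(rng)
        meds = _draw_meds(rng)
        # baseline UCEIS in 1..3 / 4..7 so every outcome stays within 0..8
        b_uceis = int(rng.integers(1, 4)) if base_class[i] == "low" else int(rng.integers(4, 8))
        if outcome[i] == "improved":
            delta = -int(min(rng.integers(1, 3), b_uceis))
        elif outcome[i] == "worsened":
            delta = int(min(rng.integers(1, 3), 8 - b_uceis))
        else:
            delta = 0
        f_uceis = b_uceis + delta
        for timepoint, uceis in (("baseline", b_uceis), ("followup", f_uceis)):
            sample_counter += 1
            cls = "low" if uceis <= 3 else "high"
            mean = base * subject_factor
            if cls == "high":
                mean = mean * uceis_mult
            if timepoint == "baseline":
                if outcome[i] == "worsened":
                    mean = mean * prog_mult
                elif outcome[i] == "nochange":
                    mean = mean * np.sqrt(prog_mult)
            spectrum = render_spectrum(
                pd.Series(mean, index=metabolites),
                library=library,
                acq=acq,
                rng=rng,
                jitter_sd=cohort.shift_jitter_sd,
                noise_sd=cohort.noise_sd,
                drift_amplitude=cohort.baseline_drift_amplitude,
                global_shift_sd=cohort.global_shift_sd,
            )
            spectra.append(spectrum_to_fid(spectrum, acq) if return_fids else spectrum)
            row: dict[str, object] = {
                "sample_id": f"S{sample_counter:03d}",
                "subject_id": subj,
                "timepoint": timepoint,
                "class_label": cls,
                "uceis": uceis,
                "nancy": _nancy_for_class(rng, cls),
                "sccai": int(rng.integers(0, 11)),
            }
            row.update(_draw_bloods(rng))
            row.update(meds)
            row.update(demo)
            rows.append(row)
    metadata = pd.DataFrame(rows, columns=METADATA_COLUMNS)
    metadata.attrs["outcome"] = {f"P{i + 1:03d}": outcome[i] for i in range(n_subjects)}
    return spectra, metadata
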