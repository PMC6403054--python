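"""Metabolite signature library and contrast effect tables.

A :class:`MetaboliteSignature` describes how one metabolite appears in a
plasma ¹H CPMG spectrum: one or more multiplet resonances, each with a
chemical-shift centre, relative line intensities, line spacing, Lorentzian
linewidth and an effective proton count.  The packaged library
(``data/metabolite_library.yml``) covers the lipoprotein envelopes and small
metabolites relevant to ulcerative-colitis plasma profiling, plus the lactate
doublet at 1.33 ppm used for chemical-shift referencing.  Shifts and
multiplets are editable literature defaults.

An :class:`EffectTable` holds the signed percent change of each affected
metabolite between a case and a control class; the packaged tables
(``data/effect_tables.yml``) encode the three clinical contrasts (endoscopic
activity, histological activity, prognosis).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "Resonance",
    "MetaboliteSignature",
    "EffectTable",
    "default_metabolite_library",
    "load_metabolite_library",
    "default_effect_tables",
    "packaged_effect_table",
    "library_index",
    "default_baseline_concentrations",
]


@dataclass(frozen=True)
class Resonance:
    """One (possibly multiplet) resonance of a metabolite."""

    center: float  # ppm
    pattern: tuple[float, ...]  # relative line intensities, normalized to sum 1
    line_spacing: float  # ppm between adjacent lines
    linewidth: float  # Hz, FWHM
    proton_weight: float  # effective proton count

    def __post_init__(self) -> None:
        if not 0.0 <= self.center <= 9.0:
            raise ValueError(f"resonance center {self.center} ppm outside [0, 9]")
        if self.linewidth <= 0:
            raise ValueError("linewidth must be > 0")
        if self.proton_weight <= 0:
            raise ValueError("proton_weight must be > 0")
        pat = np.asarray(self.pattern, dtype=float)
        if pat.size == 0 or np.any(pat <= 0):
            raise ValueError("pattern intensities must be positive")
        total = float(pat.sum())
        if abs(total - 1.0) > 1e-12:
            object.__setattr__(self, "pattern", tuple(pat / total))

    def line_positions(self, shift: float = 0.0) -> np.ndarray:
        """ppm positions of the individual multiplet lines."""
        k = np.arange(len(self.pattern), dtype=float)
        return self.center + shift + (k - (len(self.pattern) - 1) / 2.0) * self.line_spacing


@dataclass(frozen=True)
class MetaboliteSignature:
    name: str
    resonances: tuple[Resonance, ...]
    kind: str = "metabolite"  # metabolite | lipoprotein | reference
    primary_ppm: float | None = None
    baseline_concentration: float | None = None
    lineshape: str = "lorentzian"


def _parse_library(doc: dict) -> list[MetaboliteSignature]:
    out = []
    for entry in doc["metabolites"]:
        resonances = tuple(
            Resonance(
                center=float(r["center"]),
                pattern=tuple(float(v) for v in r["pattern"]),
                line_spacing=float(r["line_spacing"]),
                linewidth=float(r["linewidth"]),
                proton_weight=float(r["proton_weight"]),
            )
            for r in entry["resonances"]
        )
        out.append(
            MetaboliteSignature(
                name=str(entry["name"]),
                resonances=resonances,
                kind=str(entry.get("kind", "metabolite")),
                primary_ppm=entry.get("primary_ppm"),
                baseline_concentration=entry.get("baseline_concentration"),
            )
        )
    return out


def load_metabolite_library(path: str | Path) -> list[MetaboliteSignature]:
    """Load a signature library from a YAML file (same schema as the packaged one)."""
    with open(path) as fh:
        return _parse_library(yaml.safe_load(fh))


def default_metabolite_library() -> list[MetaboliteSignature]:
    """The packaged plasma CPMG library (13 clinical species + lactate reference)."""
    text = resources.files("ucnmr.data").joinpath("metabolite_library.yml").read_text()
    return _parse_library(yaml.safe_load(text))


def library_index(library: list[MetaboliteSignature]) -> dict[str, MetaboliteSignature]:
    return {sig.name: sig for sig in library}


def default_baseline_concentrations(
    library: list[MetaboliteSignature] | None = None,
) -> dict[str, float]:
    """Default cohort-mean concentrations (arbitrary units) from the library file."""
    library = library if library is not None else default_metabolite_library()
    return {
        sig.name: float(sig.baseline_concentration)
        for sig in library
        if sig.baseline_concentration is not None
    }


@dataclass(frozen=True)
class EffectTable:
    """Signed percent change of case-class metabolite means vs the control class."""

    contrast_name: str
    entries: dict[str, float]
    case_class: str = "case"
    control_class: str = "control"

    def __post_init__(self) -> None:
        for name, pct in self.entries.items():
            if pct <= -100.0:
                raise ValueError(f"percent change for {name!r} must be > -100")

    def validate_against(self, library: list[MetaboliteSignature]) -> None:
        known = {sig.name for sig in library}
        missing = sorted(set(self.entries) - known)
        if missing:
            raise ValueError(f"effect table names unknown metabolites: {missing}")

    def multiplier(self, metabolite: str) -> float:
        """Case-over-control concentration ratio for one metabolite (1.0 if unaffected)."""
        return 1.0 + self.entries.get(metabolite, 0.0) / 100.0

    @staticmethod
    def null(contrast_name: str = "null") -> "EffectTable":
        return EffectTable(contrast_name=contrast_name, entries={})


def default_effect_tables() -> dict[str, EffectTable]:
    """The three packaged clinical contrasts."""
    text = resources.files("ucnmr.data").joinpath("effect_tables.yml").read_text()
    doc = yaml.safe_load(text)
    out = {}
    for name, block in doc["contrasts"].items():
        out[name] = EffectTable(
            contrast_name=name,
            entries={str(k): float(v) for k, v in block["entries"].items()},
            case_class=str(block["case_class"]),
            control_class=str(block["control_class"]),
        )
    return out


def packaged_effect_table(name: str) -> EffectTable:
    tables = default_effect_tables()
    if name not in tables:
        raise KeyError(f"no packaged effect table {name!r}; available: {sorted(tables)}")
    return tables[name]
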