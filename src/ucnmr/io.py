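"""Readers and writers for the formats the pipeline exchanges.

Spectra travel as JCAMP-DX (``##XYDATA=(X++(Y..Y))``, AFFN values) or as
two-column ppm/intensity CSV; bucket tables as CSV with a bucket-centre
header row; scaling models as JSON; metadata as plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .processing import BucketTable, ScalingModel, Spectrum

__all__ = [
    "write_jcampdx",
    "read_jcampdx",
    "write_spectrum_csv",
    "read_spectrum_csv",
    "write_bucket_table_csv",
    "read_bucket_table_csv",
    "write_scaling_model_json",
    "read_scaling_model_json",
]


def write_jcampdx(path: str | Path, spectrum: Spectrum, title: str = "simulated spectrum") -> None:
    """Write a spectrum as a minimal JCAMP-DX 5.00 XYDATA record (ppm axis)."""
    ppm = spectrum.ppm
    y = spectrum.intensities
    ymax = float(np.abs(y).max()) or 1.0
    yfactor = ymax / (2**30)
    yint = np.round(y / yfactor).astype(np.int64)
    n = ppm.size
    lines = [
        "##TITLE=" + title,
        "##JCAMP-DX=5.00",
        "##DATA TYPE=NMR SPECTRUM",
        "##XUNITS=PPM",
        "##YUNITS=ARBITRARY UNITS",
        f"##NPOINTS={n}",
        f"##FIRSTX={ppm[0]:.8f}",
        f"##LASTX={ppm[-1]:.8f}",
        "##XFACTOR=1.0",
        f"##YFACTOR={yfactor:.12e}",
        "##XYDATA=(X++(Y..Y))",
    ]
    per_line = 8
    for start in range(0, n, per_line):
        chunk = yint[start:start + per_line]
        lines.append(f"{ppm[start]:.8f} " + " ".join(str(v) for v in chunk))
    lines.append("##END=")
    Path(path).write_text("\n".join(lines) + "\n")


def read_jcampdx(path: str | Path) -> Spectrum:
    """Read a JCAMP-DX XYDATA spectrum written by :func:`write_jcampdx`."""
    header: dict[str, str] = {}
    y_values: list[float] = []
    in_data = False
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper()
            if key == "XYDATA":
                in_data = True
                continue
            if key == "END":
                break
            header[key] = value.strip()
            in_data = False
            continue
        if in_data:
            parts = line.split()
            y_values.extend(float(v) for v in parts[1:])  # first token is the X check value
    n = int(header["NPOINTS"])
    if len(y_values) != n:
        raise ValueError(f"expected {n} Y values, parsed {len(y_values)}")
    yfactor = float(header.get("YFACTOR", "1.0"))
    first_x = float(header["FIRSTX"])
    last_x = float(header["LASTX"])
    ppm = np.linspace(first_x, last_x, n)
    return Spectrum(ppm=ppm, intensities=np.asarray(y_values) * yfactor)


def write_spectrum_csv(path: str | Path, spectrum: Spectrum) -> None:
    pd.DataFrame({"ppm": spectrum.ppm, "intensity": spectrum.intensities}).to_csv(
        path, index=False
    )


def read_spectrum_csv(path: str | Path) -> Spectrum:
    df = pd.read_csv(path)
    return Spectrum(ppm=df["ppm"].to_numpy(), intensities=df["intensity"].to_numpy())


def write_bucket_table_csv(path: str | Path, table: BucketTable) -> None:
    """Bucket table as CSV: header row of bucket centres (2-decimal ppm)."""
    df = pd.DataFrame(
        table.values,
        index=pd.Index(table.sample_ids, name="sample_id"),
        columns=[f"{c:.2f}" for c in table.bucket_centers],
    )
    df.to_csv(path)


def read_bucket_table_csv(path: str | Path, scaled: bool = False) -> BucketTable:
    df = pd.read_csv(path, index_col=0)
    return BucketTable(
        values=df.to_numpy(dtype=float),
        bucket_centers=np.array([float(c) for c in df.columns]),
        sample_ids=[str(s) for s in df.index],
        scaled=scaled,
    )


def write_scaling_model_json(path: str | Path, model: ScalingModel) -> None:
    payload = {
        "mean": model.mean.tolist(),
        "divisor": model.divisor.tolist(),
        "zero_sd": model.zero_sd.astype(bool).tolist(),
        "fitted_on": list(model.fitted_on),
    }
    Path(path).write_text(json.dumps(payload))


def read_scaling_model_json(path: str | Path) -> ScalingModel:
    payload = json.loads(Path(path).read_text())
    return ScalingModel(
        mean=np.asarray(payload["mean"], dtype=float),
        divisor=np.asarray(payload["divisor"], dtype=float),
        zero_sd=np.asarray(payload["zero_sd"], dtype=bool),
        fitted_on=list(payload["fitted_on"]),
    )
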