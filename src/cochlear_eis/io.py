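"""Plain-text interchange formats.

* spectra CSV: columns stim, rec, frequency_hz, z_real_ohm, z_imag_ohm
* parameter JSON: list of {stim, rec, variant, R1, Y1, p1, R2, Y2, p2}
  (SI units: ohms, S*s^p, dimensionless); R1 is null for bare-CPE1 models
* waveform CSV: columns time_s, voltage_v, provenance

Leading ``#`` comment lines carry provenance metadata (seed, noise level)
so that fixed-seed outputs are byte-reproducible and self-describing.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .circuit import BlockVariant, ElectrodePairKey, TransimpedanceModel
from .fitting import EISSpectrum, FitResult
from .transient import Provenance, VoltageWaveform

__all__ = [
    "write_spectra_csv",
    "read_spectra_csv",
    "write_models_json",
    "read_models_json",
    "write_fits_json",
    "write_waveform_csv",
    "read_waveform_csv",
    "write_profiles_csv",
]

_FLOAT_FMT = "%.12e"


def _header_lines(meta: Mapping | None) -> str:
    if not meta:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in sorted(meta.items()))


def write_spectra_csv(
    path: str | Path,
    spectra: Mapping[ElectrodePairKey, EISSpectrum],
    meta: Mapping | None = None,
) -> None:
    rows = []
    for key in sorted(spectra):
        sp = spectra[key]
        for f, z in zip(sp.frequencies, sp.impedances):
            rows.append((key.stim, key.rec, f, z.real, z.imag))
    df = pd.DataFrame(rows, columns=["stim", "rec", "frequency_hz", "z_real_ohm", "z_imag_ohm"])
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def read_spectra_csv(path: str | Path) -> dict[ElectrodePairKey, EISSpectrum]:
    df = pd.read_csv(path, comment="#")
    out = {}
    for (stim, rec), grp in df.groupby(["stim", "rec"]):
        grp = grp.sort_values("frequency_hz")
        key = ElectrodePairKey(stim=int(stim), rec=int(rec))
        out[key] = EISSpectrum(
            frequencies=grp["frequency_hz"].to_numpy(),
            impedances=grp["z_real_ohm"].to_numpy() + 1j * grp["z_imag_ohm"].to_numpy(),
            pair=key,
        )
    return out


def _model_record(key: ElectrodePairKey, model: TransimpedanceModel) -> dict:
    return {
        "stim": key.stim,
        "rec": key.rec,
        "variant": model.variant.value,
        "R1": model.R1,
        "Y1": model.Y1,
        "p1": model.p1,
        "R2": model.R2,
        "Y2": model.Y2,
        "p2": model.p2,
    }


def write_models_json(
    path: str | Path,
    models: Mapping[ElectrodePairKey, TransimpedanceModel],
    meta: Mapping | None = None,
) -> None:
    payload = {
        "meta": dict(meta or {}),
        "models": [_model_record(k, models[k]) for k in sorted(models)],
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_models_json(path: str | Path) -> dict[ElectrodePairKey, TransimpedanceModel]:
    payload = json.loads(Path(path).read_text())
    records = payload["models"] if isinstance(payload, dict) else payload
    out = {}
    for rec in records:
        key = ElectrodePairKey(stim=int(rec["stim"]), rec=int(rec["rec"]))
        out[key] = TransimpedanceModel.from_values(
            R1=rec.get("R1"),
            Y1=rec["Y1"],
            p1=rec["p1"],
            R2=rec["R2"],
            Y2=rec["Y2"],
            p2=rec["p2"],
            variant=BlockVariant(rec.get("variant", "parallel_rcpe1")),
        )
    return out


def write_fits_json(
    path: str | Path,
    fits: Mapping[ElectrodePairKey, FitResult],
    meta: Mapping | None = None,
) -> None:
    """Fit results: parameters plus standard errors and residual norms."""
    records = []
    for key in sorted(fits):
        fr = fits[key]
        rec = _model_record(key, fr.model)
        rec.update(
            stderr={k: (None if np.isnan(v) else v) for k, v in fr.stderr.items()},
            residual_norm=fr.residual_norm,
            success=fr.success,
            weighting=fr.weighting,
            n_points=fr.n_points,
        )
        records.append(rec)
    payload = {"meta": dict(meta or {}), "models": records}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_waveform_csv(
    path: str | Path, waveform: VoltageWaveform, meta: Mapping | None = None
) -> None:
    df = pd.DataFrame(
        {
            "time_s": waveform.times,
            "voltage_v": waveform.voltages,
            "provenance": waveform.provenance.value,
        }
    )
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def read_waveform_csv(path: str | Path) -> VoltageWaveform:
    df = pd.read_csv(path, comment="#")
    prov = Provenance(df["provenance"].iloc[0]) if "provenance" in df else Provenance.MEASURED
    return VoltageWaveform(
        times=df["time_s"].to_numpy(), voltages=df["voltage_v"].to_numpy(), provenance=prov
    )


def write_profiles_csv(
    path: str | Path, profiles: pd.DataFrame, meta: Mapping | None = None
) -> None:
    """Tidy per-pair parameter table (stim, rec, parameter, value)."""
    long = profiles.melt(
        id_vars=["stim", "rec"], var_name="parameter", value_name="value"
    ).sort_values(["stim", "rec", "parameter"])
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        long.to_csv(fh, index=False, float_format=_FLOAT_FMT, lineterminator="\n")
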