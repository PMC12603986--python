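"""Plain-text I/O: CSV tables, YAML configs and an array container.

Concentration columns are tagged with their unit in the header
(``*_uM``, ``volume_uL``); everything is converted to internal SI molar /
µL on read.  The tensor container is a NumPy ``.npz`` holding the intensity
array, both axes and the per-step compositions — a documented array file,
with a long-format CSV alternative for interchange.  No proprietary
instrument formats are read.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, InputError
from .itc import ITCProtocol, Thermogram
from .speciation import BindingModel, MixtureComposition
from .trlfs import TRLFSDataset

__all__ = [
    "write_compositions_csv", "read_compositions_csv",
    "write_thermogram_csv", "read_thermogram_csv",
    "dataset_to_long_csv", "dataset_from_long_csv",
    "save_dataset", "load_dataset",
    "read_binding_model", "write_binding_model",
    "read_config",
]


def write_compositions_csv(path: str | Path,
                           compositions: list[MixtureComposition],
                           volumes_ul: list[float] | None = None) -> None:
    rows = []
    for i, c in enumerate(compositions):
        rows.append({
            "step": i,
            "l_tot_uM": c.l_tot * 1e6,
            "m_tot_uM": c.m_tot * 1e6,
            "n_tot_uM": c.n_tot * 1e6,
            "volume_uL": volumes_ul[i] if volumes_ul else float("nan"),
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_compositions_csv(path: str | Path,
                          competitor_model: BindingModel | None = None,
                          drop_competitor: bool = False
                          ) -> list[MixtureComposition]:
    """Read per-step totals.

    A competitor column requires its binding model to rebuild a full
    composition; ``drop_competitor=True`` discards the competitor totals
    instead — appropriate when only the (Eu-selective) measurement is being
    re-analysed and the competitor model is exactly what is unknown.
    """
    df = pd.read_csv(path)
    required = {"step", "l_tot_uM", "m_tot_uM"}
    if not required.issubset(df.columns):
        raise InputError(f"compositions CSV needs columns {sorted(required)}")
    out = []
    for _, row in df.sort_values("step").iterrows():
        n_tot = float(row.get("n_tot_uM", 0.0) or 0.0) * 1e-6
        if drop_competitor:
            n_tot = 0.0
        if n_tot > 0 and competitor_model is None:
            raise InputError(
                f"{path}: competitor present (n_tot_uM > 0) but no "
                "competitor_model given; pass one or drop_competitor=True")
        out.append(MixtureComposition(
            l_tot=float(row["l_tot_uM"]) * 1e-6,
            m_tot=float(row["m_tot_uM"]) * 1e-6,
            n_tot=n_tot,
            competitor_model=competitor_model if n_tot > 0 else None,
        ))
    return out


def write_thermogram_csv(path: str | Path, protocol: ITCProtocol,
                         thermogram: Thermogram) -> None:
    pd.DataFrame({
        "injection": np.arange(1, thermogram.heats.size + 1),
        "volume_uL": list(protocol.injection_volumes_ul),
        "heat_uJ": thermogram.heats,
        "included": thermogram.included.astype(int),
    }).to_csv(path, index=False)


def read_thermogram_csv(path: str | Path) -> tuple[np.ndarray, Thermogram]:
    df = pd.read_csv(path)
    required = {"injection", "volume_uL", "heat_uJ"}
    if not required.issubset(df.columns):
        raise InputError(f"thermogram CSV needs columns {sorted(required)}")
    df = df.sort_values("injection")
    included = (df["included"].to_numpy().astype(bool)
                if "included" in df.columns else None)
    return (df["volume_uL"].to_numpy(dtype=float),
            Thermogram(heats=df["heat_uJ"].to_numpy(dtype=float),
                       included=included))


def dataset_to_long_csv(path: str | Path, data: TRLFSDataset) -> None:
    """Export a titration tensor as long-format rows (one per voxel)."""
    s, j, k = data.intensity.shape
    step, wl, dl = np.meshgrid(np.arange(s), data.wavelengths, data.delays,
                               indexing="ij")
    pd.DataFrame({
        "step": step.ravel(),
        "wavelength_nm": wl.ravel(),
        "delay_us": dl.ravel(),
        "intensity": data.intensity.ravel(),
    }).to_csv(path, index=False)


def dataset_from_long_csv(path: str | Path,
                          compositions: list[MixtureComposition],
                          excitation_nm: float = 394.0) -> TRLFSDataset:
    df = pd.read_csv(path)
    required = {"step", "wavelength_nm", "delay_us", "intensity"}
    if not required.issubset(df.columns):
        raise InputError(f"long-format CSV needs columns {sorted(required)}")
    steps = np.sort(df["step"].unique())
    wl = np.sort(df["wavelength_nm"].unique())
    dl = np.sort(df["delay_us"].unique())
    cube = (df.pivot_table(index=["step", "wavelength_nm"],
                           columns="delay_us", values="intensity")
            .to_numpy().reshape(steps.size, wl.size, dl.size))
    return TRLFSDataset(intensity=cube, wavelengths=wl, delays=dl,
                        compositions=compositions, excitation_nm=excitation_nm)


def save_dataset(path: str | Path, data: TRLFSDataset) -> None:
    """Persist a titration tensor with axes and composition metadata (.npz)."""
    np.savez(
        path,
        intensity=data.intensity,
        wavelengths=data.wavelengths,
        delays=data.delays,
        excitation_nm=np.array([data.excitation_nm]),
        compositions=np.array([[c.l_tot, c.m_tot, c.n_tot]
                               for c in data.compositions]),
    )


def load_dataset(path: str | Path,
                 competitor_model: BindingModel | None = None) -> TRLFSDataset:
    with np.load(path) as z:
        comps = [
            MixtureComposition(
                l_tot=float(l), m_tot=float(m), n_tot=float(n),
                competitor_model=competitor_model if n > 0 else None)
            for l, m, n in z["compositions"]
        ]
        return TRLFSDataset(intensity=z["intensity"],
                            wavelengths=z["wavelengths"],
                            delays=z["delays"],
                            compositions=comps,
                            excitation_nm=float(z["excitation_nm"][0]))


def save_trlfs_dir(out_dir: str | Path, data: TRLFSDataset) -> Path:
    """Write a titration as a directory bundle (long CSV + compositions + meta)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset_to_long_csv(out / "intensity_long.csv", data)
    write_compositions_csv(out / "compositions.csv", data.compositions)
    (out / "meta.yaml").write_text(yaml.safe_dump(
        {"excitation_nm": data.excitation_nm, "kind": "trlfs"}))
    return out


def load_trlfs_dir(in_dir: str | Path,
                   drop_competitor: bool = False) -> TRLFSDataset:
    d = Path(in_dir)
    meta = yaml.safe_load((d / "meta.yaml").read_text()) if (d / "meta.yaml").exists() else {}
    comps = read_compositions_csv(d / "compositions.csv",
                                  drop_competitor=drop_competitor)
    return dataset_from_long_csv(d / "intensity_long.csv", comps,
                                 excitation_nm=float(meta.get("excitation_nm", 394.0)))


def save_itc_dir(out_dir: str | Path,
                 replicates: list[tuple[ITCProtocol, Thermogram]]) -> Path:
    """Write calorimetric replicates as per-replicate CSVs + one protocol file."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    protocols = []
    for i, (protocol, thermo) in enumerate(replicates):
        write_thermogram_csv(out / f"thermogram_{i}.csv", protocol, thermo)
        protocols.append({
            "cell_volume_uL": protocol.cell_volume_ul,
            "cell_peptide_uM": protocol.cell_peptide * 1e6,
            "syringe_metal_uM": protocol.syringe_metal * 1e6,
            "temperature_K": protocol.temperature,
            "thermogram": f"thermogram_{i}.csv",
        })
    (out / "protocols.yaml").write_text(yaml.safe_dump({"replicates": protocols}))
    return out


def load_itc_dir(in_dir: str | Path) -> list[tuple[ITCProtocol, Thermogram]]:
    d = Path(in_dir)
    doc = yaml.safe_load((d / "protocols.yaml").read_text())
    if not isinstance(doc, dict) or "replicates" not in doc:
        raise ConfigError(f"{d}/protocols.yaml: expected a 'replicates' list")
    out = []
    for entry in doc["replicates"]:
        volumes, thermo = read_thermogram_csv(d / entry["thermogram"])
        protocol = ITCProtocol(
            cell_volume_ul=float(entry["cell_volume_uL"]),
            cell_peptide=float(entry["cell_peptide_uM"]) * 1e-6,
            syringe_metal=float(entry["syringe_metal_uM"]) * 1e-6,
            injection_volumes_ul=tuple(volumes),
            temperature=float(entry.get("temperature_K", 298.15)),
        )
        out.append((protocol, thermo))
    return out


def write_binding_model(path: str | Path, model: BindingModel) -> None:
    doc = {"label": model.label, "kd_11_M": model.kd_11,
           "kd_12_M": None if math.isinf(model.kd_12) else model.kd_12}
    Path(path).write_text(yaml.safe_dump(doc))


def read_binding_model(path: str | Path) -> BindingModel:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or "kd_11_M" not in doc:
        raise ConfigError(f"{path}: expected a mapping with kd_11_M")
    try:
        kd12 = doc.get("kd_12_M")
        return BindingModel(kd_11=float(doc["kd_11_M"]),
                            kd_12=math.inf if kd12 is None else float(kd12),
                            label=str(doc.get("label", "")))
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: invalid binding model ({exc})") from exc


def read_config(path: str | Path) -> dict:
    """Load and minimally validate a pipeline/scenario YAML config."""
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    try:
        doc = yaml.safe_load(p.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{p}: invalid YAML ({exc})") from exc
    if not isinstance(doc, dict):
        raise ConfigError(f"{p}: top level must be a mapping")
    return doc
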