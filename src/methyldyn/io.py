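"""Table readers/writers, structure loading, run configuration and
provenance logging.

All tables are UTF-8, comma-separated, with a header row, '.' decimal and
``NA`` for missing values.  Dialects:

* plane tables — the PLANE_COLUMNS schema of :mod:`methyldyn.relax`;
* rate tables — residue_id, R1, R1_err, R2, R2_err, NOE, NOE_err;
* S2 tables — probe_id, state, S2_axis, S2_err (extra columns preserved);
* coupling tables — residue_id, J_Hz, J_err;
* shift tables — probe_id, H_ppm, C_ppm;
* sPRE tables — probe_id, intensity_0mM, intensity_2mM, errors, depth_A.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
import yaml

from .relax import PLANE_COLUMNS, PlaneIntensityTable

_CSV_KW = dict(index=False, na_rep="NA")


class ConfigError(ValueError):
    pass


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, **_CSV_KW)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, na_values=["NA"], keep_default_na=True)


def write_plane_table(table: PlaneIntensityTable, path) -> None:
    df = table.df[PLANE_COLUMNS].copy()
    out = Path(path)
    out.parent.mkdir(parents=True, exist_ok=True)
    with open(out, "w", encoding="utf-8") as fh:
        for key, val in sorted(table.meta.items()):
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, **_CSV_KW)


def read_plane_table(path) -> PlaneIntensityTable:
    import io as _io

    meta = {}
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    body = 0
    for line in lines:
        if not line.startswith("#"):
            break
        key, _, val = line[1:].partition(":")
        meta[key.strip()] = _coerce(val.strip())
        body += 1
    df = pd.read_csv(_io.StringIO("".join(lines[body:])), na_values=["NA"])
    return PlaneIntensityTable(df, meta=meta)


def _coerce(s: str):
    for cast in (int, float):
        try:
            return cast(s)
        except ValueError:
            pass
    return s


# ---------------------------------------------------------------------------
# run configuration

_CONFIG_KEYS = {
    "datasets": dict,
    "probe_sets": dict,
    "constants": dict,
    "model": dict,
    "seeds": dict,
    "structures": dict,
    "solvent": str,
    "output_dir": str,
    "residue_offset": int,
}

_CONSTANT_KEYS = {
    "qcc_hz", "s_d", "temperature_K", "n_chi", "viscosity_ratio",
    "noe_cutoff", "err_max_dS2",
}


def validate_config(cfg: dict) -> dict:
    """Validate a run configuration against the documented key set; unknown
    keys are rejected (typo safety)."""
    if not isinstance(cfg, dict):
        raise ConfigError("configuration root must be a mapping")
    for key, val in cfg.items():
        if key not in _CONFIG_KEYS:
            raise ConfigError(
                f"unknown configuration key {key!r}; known: {sorted(_CONFIG_KEYS)}"
            )
        if not isinstance(val, _CONFIG_KEYS[key]):
            raise ConfigError(
                f"configuration key {key!r} must be {_CONFIG_KEYS[key].__name__}"
            )
    for key in cfg.get("constants", {}):
        if key not in _CONSTANT_KEYS:
            raise ConfigError(
                f"unknown constant {key!r}; known: {sorted(_CONSTANT_KEYS)}"
            )
    return cfg


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    return validate_config(cfg)


def provenance(cfg: dict | None, seed: int | None) -> dict:
    """Machine-readable run log: config hash, seed and versions."""
    import methyldyn

    blob = json.dumps(cfg or {}, sort_keys=True).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "methyldyn": methyldyn.__version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "python": platform.python_version(),
    }


def write_provenance(path, cfg: dict | None, seed: int | None) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(provenance(cfg, seed), fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# structures


class StructureFormatError(ValueError):
    pass


def read_structure(path, residue_offset: int = 0) -> gemmi.Structure:
    """Load a PDB or mmCIF structure.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties to the first altloc in label order); ``residue_offset`` shifts
    every residue number, reconciling construct numbering (e.g. tag-cleavage
    leftovers) with the deposited model.
    """
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as e:
        raise StructureFormatError(f"cannot parse {path}: {e}") from None
    st.setup_entities()
    _resolve_altlocs(st)
    if residue_offset:
        for model in st:
            for chain in model:
                for res in chain:
                    res.seqid.num += residue_offset
    return st


def _resolve_altlocs(st: gemmi.Structure) -> None:
    for model in st:
        for chain in model:
            for res in chain:
                groups: dict[str, list] = {}
                for atom in res:
                    groups.setdefault(atom.name, []).append(atom)
                drop = []
                for name, atoms in groups.items():
                    if len(atoms) > 1:
                        keep = max(
                            atoms,
                            key=lambda a: (a.occ, -ord(a.altloc or "~")),
                        )
                        drop += [a for a in atoms if a is not keep]
                        keep.altloc = "\0"
                    elif atoms[0].altloc not in ("\0", ""):
                        atoms[0].altloc = "\0"
                if drop:
                    names = {id(a) for a in drop}
                    for i in reversed(range(len(res))):
                        if id(res[i]) in names:
                            del res[i]
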