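"""Plain-text readers/writers and the run manifest.

Band matrices travel as TSV (first column ``sample_id``, then the
metadata columns day/glucose_x/silicate/nitrogen_source, then 0/1 band
columns); parameter sets as YAML key-value files mirroring the published
symbol names.  Every CLI run writes a JSON manifest (argument values,
seeds, input hashes, package version, warnings) sufficient to reproduce
its outputs exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from .fingerprints import METADATA_COLUMNS, BandMatrix
from .parameters import FoodWebParameters

logger = logging.getLogger("pentaweb")

__all__ = [
    "read_params",
    "write_params",
    "read_band_matrix",
    "write_band_matrix",
    "write_manifest",
]

_PARAM_FIELDS = ("alpha_B", "alpha_A", "alpha_H", "alpha_C",
                 "Y_H", "Y_BC", "sigma", "Q10", "psi", "T_ref")


def read_params(path) -> FoodWebParameters:
    """Load a parameter set from a YAML key-value file.

    ``Y_BC`` and ``psi`` have no published values and must be present;
    their absence is a hard error.  Unknown keys are ignored with a
    warning; invariants (positivity, yield and Q10 ranges) are enforced
    on load.
    """
    path = Path(path)
    with path.open() as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping of parameter names to values")
    for required in ("Y_BC", "psi"):
        if required not in raw:
            raise ValueError(
                f"{path}: missing {required!r} — this quantity has no "
                "published value and must be supplied by configuration")
    unknown = set(raw) - set(_PARAM_FIELDS)
    if unknown:
        logger.warning("%s: ignoring unknown parameter keys %s",
                       path, sorted(unknown))
    missing = [f for f in _PARAM_FIELDS if f not in raw and f != "T_ref"]
    if missing:
        raise ValueError(f"{path}: missing parameter(s) {missing}")
    kwargs = {k: float(raw[k]) for k in _PARAM_FIELDS if k in raw}
    return FoodWebParameters(**kwargs)


def write_params(params: FoodWebParameters, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        yaml.safe_dump({k: float(v) for k, v in params.as_dict().items()},
                       fh, sort_keys=False)


_META_DTYPES = {"day": int, "glucose_x": float, "silicate": bool,
                "nitrogen_source": str}


def read_band_matrix(path) -> BandMatrix:
    """Read a band-matrix TSV; validates binary values and unique ids.

    Missing metadata columns get documented defaults with a logged
    warning.  A non-binary cell or duplicate id raises with the offending
    row/column named.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in frame.columns:
        raise ValueError(f"{path}: first column must be 'sample_id'")
    frame = frame.set_index("sample_id")
    if frame.index.has_duplicates:
        dupes = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sample ids {dupes}")

    meta_cols = [c for c in METADATA_COLUMNS if c in frame.columns]
    missing_meta = [c for c in METADATA_COLUMNS if c not in frame.columns]
    if missing_meta:
        logger.warning("%s: metadata column(s) %s missing; using defaults %s",
                       path, missing_meta,
                       {c: METADATA_COLUMNS[c] for c in missing_meta})
    metadata = frame[meta_cols].copy()
    for col in meta_cols:
        metadata[col] = metadata[col].astype(_META_DTYPES[col])

    bands = frame.drop(columns=meta_cols)
    if bands.shape[1] == 0:
        raise ValueError(f"{path}: no band columns found")
    for col in bands.columns:
        values = pd.to_numeric(bands[col], errors="coerce")
        bad = bands.index[~values.isin([0, 1])]
        if len(bad):
            raise ValueError(
                f"{path}: non-binary value {bands.loc[bad[0], col]!r} "
                f"at sample {bad[0]!r}, band {col!r}")
        bands[col] = values.astype(int)
    return BandMatrix(bands, metadata)


def write_band_matrix(matrix: BandMatrix, path) -> None:
    """Write a band matrix as TSV; round-trips bit-identically via read."""
    path = Path(path)
    out = pd.concat([matrix.metadata, matrix.values], axis=1)
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def _hash_file(path: Path) -> str:
    digest = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def write_manifest(out_dir, command: str, arguments: dict,
                   seed: int | None = None,
                   input_files: list | None = None,
                   warnings: list | None = None) -> Path:
    """Write ``manifest.json`` describing one reproducible run."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "pentaweb",
        "version": __version__,
        "command": command,
        "arguments": {k: (str(v) if isinstance(v, Path) else v)
                      for k, v in arguments.items()},
        "seed": seed,
        "inputs": {str(p): _hash_file(Path(p)) for p in (input_files or [])},
        "warnings": warnings or [],
    }
    path = out_dir / "manifest.json"
    with path.open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
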