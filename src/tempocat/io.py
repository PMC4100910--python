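"""Parameter files and provenance-stamped CSV output.

Parameter files are YAML.  Every CSV written through this module starts
with ``#`` comment lines carrying the package version, the seed and a
hash of the generating parameters, so any table can be traced back to
the exact configuration that produced it.  Existing files are never
overwritten unless explicitly requested.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from .attractor import AttractorParams


class OutputExistsError(FileExistsError):
    """Refusing to overwrite an existing output file."""


def params_to_dict(params) -> dict:
    """Plain-python dict of a parameter dataclass (tuples -> lists)."""
    d = dataclasses.asdict(params)

    def clean(v):
        if isinstance(v, dict):
            return {str(k): clean(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [clean(x) for x in v]
        return v

    return clean(d)


def params_hash(params) -> str:
    """Short stable hash of a parameter set (first 12 hex digits of SHA-256)."""
    blob = json.dumps(params_to_dict(params), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def save_params(params, path, overwrite: bool = False) -> None:
    """Write a parameter dataclass to a YAML file."""
    path = Path(path)
    if path.exists() and not overwrite:
        raise OutputExistsError(f"{path} exists (pass overwrite to replace)")
    path.write_text(yaml.safe_dump(params_to_dict(params), sort_keys=True))


def load_attractor_params(path) -> AttractorParams:
    """Read network parameters from a YAML file.

    Unknown keys raise a validation error; phase_inputs values become
    tuples and rt_thresholds keys become numbers.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping of parameter names")
    known = {f.name for f in dataclasses.fields(AttractorParams)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown parameters {sorted(unknown)}")
    if "phase_inputs" in raw:
        raw["phase_inputs"] = {k: tuple(float(x) for x in v)
                               for k, v in raw["phase_inputs"].items()}
    if "rt_thresholds" in raw:
        raw["rt_thresholds"] = {float(k): float(v)
                                for k, v in raw["rt_thresholds"].items()}
    return AttractorParams(**raw)


def provenance_header(seed, params=None, **extra) -> list[str]:
    """Comment lines stamped into every output file."""
    from . import __version__

    lines = [f"# tempocat_version: {__version__}", f"# seed: {seed}"]
    if params is not None:
        lines.append(f"# params_hash: {params_hash(params)}")
    lines += [f"# {k}: {v}" for k, v in extra.items()]
    return lines


def write_table(df: pd.DataFrame, path, seed, params=None,
                overwrite: bool = False, **extra) -> Path:
    """Write a DataFrame as CSV with the provenance comment header."""
    path = Path(path)
    if path.exists() and not overwrite:
        raise OutputExistsError(f"{path} exists (pass overwrite to replace)")
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("\n".join(provenance_header(seed, params, **extra)) + "\n")
        df.to_csv(fh, index=False)
    return path


def read_table(path) -> pd.DataFrame:
    """Read a provenance-stamped CSV (metadata available via read_header)."""
    return pd.read_csv(path, comment="#")


def read_header(path) -> dict:
    """Parse the ``# key: value`` provenance header of a CSV."""
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                k, v = line[1:].split(":", 1)
                meta[k.strip()] = v.strip()
    return meta
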