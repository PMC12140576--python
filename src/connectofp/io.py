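"""Plain-text file formats and run configuration.

Everything is delimited text: recordings as whitespace-separated region x
frame matrices (regions as rows), masks as one 0/1 per line, atlases as
two-column (region_index, subnetwork_name) tables with 0-based indices,
and manifests / result tables as CSV. Matrix values are written with
enough digits to round-trip doubles exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortConfig, ConditionSpec, Recording
from .experiments import ExperimentConfig, SubnetworkDefinition

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_mask",
    "write_mask",
    "read_atlas",
    "write_atlas",
    "write_cohort",
    "read_cohort",
    "RunConfig",
]

_FMT = "%.17g"


def read_timeseries(path) -> np.ndarray:
    """Read a delimited regions x frames matrix, rejecting ragged rows and
    non-numeric cells with the offending line number."""
    path = Path(path)
    rows: list[list[float]] = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            tokens = line.replace(",", " ").split()
            try:
                row = [float(t) for t in tokens]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric entry ({exc})") from exc
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise ValueError(
                    f"{path}:{lineno}: ragged row ({len(row)} columns, "
                    f"expected {width})"
                )
            rows.append(row)
    if not rows:
        raise ValueError(f"{path}: empty matrix file")
    return np.asarray(rows, dtype=float)


def write_timeseries(path, data: np.ndarray) -> None:
    np.savetxt(path, np.asarray(data, dtype=float), fmt=_FMT, delimiter="\t")


def read_mask(path, expected_length: int) -> np.ndarray:
    """Read a one-token-per-line 0/1 keep-vector of a required length."""
    path = Path(path)
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.strip()
            if not tok:
                continue
            if tok not in ("0", "1"):
                raise ValueError(f"{path}:{lineno}: mask token must be 0 or 1, got {tok!r}")
            values.append(int(tok))
    if len(values) != expected_length:
        raise ValueError(
            f"{path}: mask length {len(values)} does not match recording "
            f"length {expected_length}"
        )
    return np.asarray(values, dtype=int)


def write_mask(path, mask: np.ndarray) -> None:
    Path(path).write_text("".join(f"{int(v)}\n" for v in mask))


def read_atlas(path) -> list[SubnetworkDefinition]:
    """Read a (region_index, subnetwork_name) table into subnetwork
    definitions; indices are 0-based, must not repeat (networks are
    nonoverlapping), and regions absent from the table belong to no
    subnetwork."""
    path = Path(path)
    seen: dict[int, str] = {}
    groups: dict[str, list[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            tokens = line.replace(",", " ").split()
            if len(tokens) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            try:
                idx = int(tokens[0])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad region index") from exc
            name = tokens[1]
            if idx in seen:
                raise ValueError(
                    f"{path}:{lineno}: region {idx} already assigned to "
                    f"{seen[idx]!r}; subnetworks must not overlap"
                )
            seen[idx] = name
            groups.setdefault(name, []).append(idx)
    return [
        SubnetworkDefinition(name=name, roi_indices=tuple(sorted(idx)))
        for name, idx in sorted(groups.items())
    ]


def write_atlas(path, atlas: Sequence[SubnetworkDefinition]) -> None:
    with open(path, "w") as fh:
        fh.write("# region_index\tsubnetwork_name (0-based region indices)\n")
        for subnet in atlas:
            for idx in subnet.roi_indices:
                fh.write(f"{idx}\t{subnet.name}\n")


def write_cohort(recordings: Sequence[Recording], out_dir) -> Path:
    """Write one matrix file (and mask file) per recording plus a manifest
    CSV; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        stem = f"{rec.subject_id}_{rec.session_id}_{rec.condition}"
        ts_path = out / f"{stem}.tsv"
        write_timeseries(ts_path, rec.data)
        mask_path = ""
        if rec.mask is not None:
            mask_path = str(out / f"{stem}.mask.txt")
            write_mask(mask_path, rec.mask)
        rows.append(
            {
                "file_path": str(ts_path),
                "subject_id": rec.subject_id,
                "session_id": rec.session_id,
                "condition": rec.condition,
                "mask_path": mask_path,
            }
        )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path) -> list[Recording]:
    """Load recordings listed in a manifest CSV; (subject, session,
    condition) must be unique and all paths must exist."""
    df = pd.read_csv(manifest_path, keep_default_na=False)
    required = {"file_path", "subject_id", "session_id", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    keys = list(zip(df.subject_id, df.session_id, df.condition))
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (subject, session, condition) in manifest")
    recordings = []
    for row in df.itertuples(index=False):
        data = read_timeseries(row.file_path)
        mask = None
        mask_path = getattr(row, "mask_path", "")
        if mask_path:
            mask = read_mask(mask_path, expected_length=data.shape[1])
        recordings.append(
            Recording(
                subject_id=str(row.subject_id),
                session_id=str(row.session_id),
                condition=str(row.condition),
                data=data,
                mask=mask,
            )
        )
    return recordings


_COHORT_KEYS = {
    "n_subjects",
    "n_sessions",
    "n_regions",
    "n_frames",
    "distinctiveness",
    "session_noise",
    "conditions",
    "censor_fraction",
    "latent_rank",
    "seed",
}
_EXPERIMENT_KEYS = {
    "method",
    "lambda",
    "eigenvalue_floor",
    "reference_condition",
    "min_subnetwork_size",
    "window_halfwidth",
    "database_k",
    "n_identification_trials",
    "n_blocks",
}
_EXTRA_KEYS = {"out_dir", "verbosity"}


class RunConfig:
    """Flat YAML run configuration covering cohort and experiment fields.

    Unknown keys are rejected. ``hash`` digests the canonical content so
    every run can embed a config fingerprint in its outputs.
    """

    def __init__(self, mapping: dict | None = None):
        mapping = dict(mapping or {})
        unknown = set(mapping) - _COHORT_KEYS - _EXPERIMENT_KEYS - _EXTRA_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        self.mapping = mapping

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls(data)

    @property
    def hash(self) -> str:
        canon = json.dumps(self.mapping, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def cohort_config(self, **overrides) -> CohortConfig:
        kwargs = {k: v for k, v in self.mapping.items() if k in _COHORT_KEYS}
        kwargs.update(overrides)
        conds = kwargs.get("conditions")
        if conds is not None:
            kwargs["conditions"] = tuple(
                ConditionSpec(
                    name=c["name"],
                    modulation=float(c.get("modulation", 0.0)),
                    regions=tuple(c.get("regions", ())),
                )
                if isinstance(c, dict)
                else ConditionSpec(str(c))
                for c in conds
            )
        return CohortConfig(**kwargs)

    def experiment_config(self, **overrides) -> ExperimentConfig:
        kwargs = {
            ("lam" if k == "lambda" else k): v
            for k, v in self.mapping.items()
            if k in _EXPERIMENT_KEYS
        }
        if "seed" in self.mapping:
            kwargs["seed"] = self.mapping["seed"]
        kwargs.update(overrides)
        return ExperimentConfig(**kwargs)
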