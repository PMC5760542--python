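"""Report writing: deterministic CSV/TSV artifacts with a hashed manifest."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .simulate import Trajectory

__all__ = ["RunConfig", "write_trajectory", "write_branch", "write_screen",
           "write_manifest"]


@dataclass(frozen=True)
class RunConfig:
    """Reproducibility envelope recorded with every output."""

    model: str = "meiosis"
    params_source: str = "bundled defaults"
    genotype: str = "wild type"
    protocol: str | None = None
    rtol: float = 1e-8
    atol: float = 1e-10
    seed: int = 0
    out_dir: str = "."
    notes: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("integrator tolerances must be positive")

    def to_dict(self):
        d = {k: getattr(self, k) for k in
             ("model", "params_source", "genotype", "protocol",
              "rtol", "atol", "seed")}
        d["notes"] = dict(self.notes)
        return d


def _write_csv(df: pd.DataFrame, path: Path, sep: str = ",") -> Path:
    df.to_csv(path, sep=sep, index=False, float_format="%.10g",
              lineterminator="\n")
    return path


def write_trajectory(tr: Trajectory, out_dir, stem: str = "trajectory"):
    """Tidy + wide CSVs and the event log for a trajectory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = [
        _write_csv(tr.to_frame(wide=True), out / f"{stem}_wide.csv"),
        _write_csv(tr.to_frame(wide=False), out / f"{stem}_tidy.csv"),
        _write_csv(pd.DataFrame(tr.events, columns=["time", "type"]),
                   out / f"{stem}_events.csv"),
    ]
    return files


def write_branch(branch, out_dir, stem: str = "branch", variables=None):
    """Branch TSV plus the bifurcation-point table (diff-able)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = [_write_csv(branch.to_frame(variables), out / f"{stem}.tsv",
                        sep="\t")]
    pts = pd.DataFrame(
        [dict(type=bp.kind, param=bp.param,
              **{f"y{i}": v for i, v in enumerate(bp.state)})
         for bp in branch.points])
    files.append(_write_csv(pts, out / f"{stem}_points.tsv", sep="\t"))
    return files


def write_screen(df: pd.DataFrame, out_dir, stem: str = "screen"):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = _write_csv(df, out / f"{stem}.csv")
    meta = {"concordance": df.attrs.get("concordance"),
            "thresholds": df.attrs.get("thresholds")}
    (out / f"{stem}_meta.json").write_text(json.dumps(meta, indent=1) + "\n")
    return [path, out / f"{stem}_meta.json"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(files, out_dir, config: RunConfig | None = None) -> Path:
    """Manifest: every artifact with its content hash + run provenance.

    Time unit is minutes and concentrations are dimensionless activity
    units throughout; that convention is recorded here once.
    """
    out = Path(out_dir)
    manifest = {
        "units": {"time": "minutes", "concentration": "dimensionless"},
        "config": config.to_dict() if config else None,
        "files": {Path(f).name: _sha256(Path(f)) for f in sorted(map(str, files))},
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return path
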