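"""Configuration loading and result serialization.

Configs are flat YAML or JSON documents whose keys mirror
:class:`~nichesim.params.ModelParams` fields plus the experiment bookkeeping
keys ``experiment`` and ``replicates``.  Results are written as tab-separated
tables (UTF-8, '.' decimal) plus a self-describing ``run.json`` record from
which the identical run can be reproduced.
"""

from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Dict, Optional, Tuple

import yaml

from . import __version__
from .experiments import SweepResult
from .params import ModelParams

__all__ = ["load_config", "write_results", "read_run_record"]

_RUN_KEYS = ("experiment", "replicates", "grid_L", "grid_r")


def load_config(
    path: Optional[str] = None, overrides: Optional[Dict] = None
) -> Tuple[ModelParams, Dict]:
    """Resolve a config file plus CLI overrides into validated parameters.

    Returns ``(params, run_spec)`` where ``run_spec`` holds the non-model
    keys (experiment id, replicate count, sweep grid).  Overrides win over
    file values; defaults follow the standard demography (R=1, b_max=10,
    d=0.1, K=1e6, B=1).  ``s`` and ``fitness_model`` carry no default and
    must be supplied.
    """
    doc: Dict = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(path)
        text = p.read_text()
        doc = json.loads(text) if p.suffix == ".json" else (yaml.safe_load(text) or {})
        if not isinstance(doc, dict):
            raise ValueError(f"config {path} must be a flat mapping")
    if overrides:
        doc.update({k: v for k, v in overrides.items() if v is not None})
    run_spec = {k: doc.pop(k) for k in list(doc) if k in _RUN_KEYS}
    missing = [k for k in ("L", "s", "fitness_model") if k not in doc]
    if missing:
        raise ValueError(f"config is missing required keys: {missing}")
    return ModelParams.from_dict(doc), run_spec


def write_results(result: SweepResult, out_dir: str) -> Dict[str, str]:
    """Write a sweep's outputs under ``out_dir``.

    Emits ``replicates.tsv`` (one row per replicate), the
    ``sweep_matrix_{p,time,completeness,t_mix}.tsv`` L-by-r matrices (rows =
    L ascending, columns = r ascending), ``run.json`` (full resolved
    parameters including the derived R_0, seeds, code version, wall time),
    and ``trajectory.tsv`` when trajectories were recorded.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: Dict[str, str] = {}

    rep_path = out / "replicates.tsv"
    result.replicates.to_csv(rep_path, sep="\t", index=False)
    written["replicates"] = str(rep_path)

    matrices = {
        "p": "p_appearance",
        "time": "mean_appearance_time",
        "completeness": "mean_completeness",
        "t_mix": "mean_t_mix",
    }
    for tag, stat in matrices.items():
        if stat in result.summary.columns and result.summary[stat].notna().any():
            m_path = out / f"sweep_matrix_{tag}.tsv"
            result.matrix(stat).to_csv(m_path, sep="\t")
            written[f"matrix_{tag}"] = str(m_path)

    record = {
        "code_version": __version__,
        "written_at_unix": int(time.time()),
        "experiment": result.experiment,
        "metadata": result.metadata,
        "summary": result.summary.to_dict(orient="records"),
    }
    run_path = out / "run.json"
    run_path.write_text(json.dumps(record, indent=2, default=_jsonify))
    written["run"] = str(run_path)
    return written


def read_run_record(path: str) -> Dict:
    """Load a ``run.json`` record; its ``metadata.params`` reconstructs the
    exact :class:`ModelParams` of the run."""
    return json.loads(Path(path).read_text())


def _jsonify(obj):
    try:
        return obj.item()  # numpy scalars
    except AttributeError:
        return str(obj)
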