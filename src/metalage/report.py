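"""Report assembly: tidy CSVs plus a markdown summary for a results bundle.

A bundle is a plain dict with any subset of the five analysis surfaces:

    {"exclusions": [ExclusionLog, ...],
     "single_metal_oa": DataFrame,      # metals -> OA
     "metal_aging": DataFrame,          # metals -> aging markers
     "marker_oa": DataFrame,            # aging markers -> OA
     "wqs": WQSResults (or dict of them keyed by outcome),
     "mediation": [MediationResults, ...],
     "config": SimulationConfig or dict, "seed": int}

Regenerating the report from the same bundle is byte-identical (no
timestamps; the manifest carries seeds and a config hash instead).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from .cohort import ExclusionLog
from .mediation import MediationResults
from .wqs import WQSResults

_SECTIONS = ("single_metal_oa", "metal_aging", "marker_oa", "wqs", "mediation")


def _config_hash(config: Any) -> str:
    if config is None:
        return "none"
    if hasattr(config, "to_yaml"):
        from dataclasses import asdict
        import numpy as np
        d = asdict(config)
        d = {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in d.items()}
    else:
        d = dict(config)
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def build_report(bundle: Mapping[str, Any], out_dir: str | Path) -> list[Path]:
    """Write tidy CSVs and a markdown summary; returns the written paths."""
    if not bundle or not any(k in bundle for k in _SECTIONS):
        raise ValueError("empty results bundle")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    md: list[str] = ["# Metal mixtures, biological aging and osteoarthritis — run report", ""]

    manifest = {
        "seed": bundle.get("seed"),
        "config_hash": _config_hash(bundle.get("config")),
        "sections": [k for k in _SECTIONS if k in bundle],
    }
    p = out / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(p)
    md += [f"- seed: `{manifest['seed']}`", f"- config hash: `{manifest['config_hash']}`", ""]

    if "exclusions" in bundle:
        logs: list[ExclusionLog] = bundle["exclusions"]
        df = pd.DataFrame([vars(e) for e in logs])
        p = out / "exclusions.csv"
        df.to_csv(p, index=False)
        written.append(p)
        md += ["## Participant selection", "",
               df.to_markdown(index=False) if hasattr(df, "to_markdown") else df.to_string(), ""]

    for key, title in (("single_metal_oa", "Single metals and OA risk"),
                       ("metal_aging", "Metals and biological aging markers"),
                       ("marker_oa", "Aging markers and OA risk")):
        if key not in bundle:
            continue
        df: pd.DataFrame = bundle[key]
        p = out / f"{key}.csv"
        df.to_csv(p, index=False)
        written.append(p)
        md += [f"## {title}", "", f"{len(df)} rows written to `{p.name}`.", ""]

    if "wqs" in bundle:
        wqs_obj = bundle["wqs"]
        items = wqs_obj.items() if isinstance(wqs_obj, dict) else [("oa", wqs_obj)]
        frames = []
        md += ["## Weighted quantile sum (mixture) models", ""]
        for outcome, res in items:
            assert isinstance(res, WQSResults)
            wf = res.weights_frame()
            wf.insert(0, "outcome", outcome)
            wf["index_or_or_beta"] = res.or_or_beta
            wf["index_ci_low"], wf["index_ci_high"] = res.ci
            wf["index_p"] = res.index_result.p_value
            frames.append(wf)
            md += [f"### outcome: {outcome}", "", "```", res.summary(), "```", ""]
        p = out / "wqs_weights.csv"
        pd.concat(frames, ignore_index=True).to_csv(p, index=False)
        written.append(p)

    if "mediation" in bundle:
        results: list[MediationResults] = bundle["mediation"]
        df = pd.DataFrame([r.as_dict() for r in results])
        p = out / "mediation.csv"
        df.to_csv(p, index=False)
        written.append(p)
        md += ["## Mediation by biological aging", ""]
        for r in results:
            md += ["```", r.summary(), "```", ""]

    p = out / "summary.md"
    p.write_text("\n".join(md))
    written.append(p)
    return written
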