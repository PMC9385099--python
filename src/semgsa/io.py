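"""Writers and readers for the tabular outputs.

The pathway summary table is written as TSV with exactly the columns
``pathway, No.nodes, No.DEGs, pert, pNA, pNI, PVAL, ADJP``; DEG lists
as JSON ``{pathway: [genes]}``; and a run manifest (JSON) records the
configuration and seed so a run can be reproduced byte for byte.
Numbers keep full double precision (p-values are floored, never
rounded to zero).
"""

from __future__ import annotations

import json
import os

import pandas as pd

from .model import GSA_COLUMNS, SEMGSAResults


def write_gsa(gsa: pd.DataFrame, path: str) -> None:
    missing = [c for c in GSA_COLUMNS if c not in gsa.columns]
    if missing:
        raise ValueError(f"gsa table missing columns: {missing}")
    gsa[GSA_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_gsa(path: str) -> pd.DataFrame:
    gsa = pd.read_csv(path, sep="\t")
    missing = [c for c in GSA_COLUMNS if c not in gsa.columns]
    if missing:
        raise ValueError(f"{path}: gsa table missing columns: {missing}")
    return gsa[GSA_COLUMNS]


def write_degs(deg: dict[str, list[str]], path: str) -> None:
    with open(path, "w") as fh:
        json.dump({k: list(v) for k, v in deg.items()}, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_degs(path: str) -> dict[str, list[str]]:
    with open(path) as fh:
        return json.load(fh)


def write_manifest(config: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(config, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")


def write_outputs(results: SEMGSAResults, outdir: str) -> dict[str, str]:
    """Write gsa.tsv, degs.json and manifest.json under ``outdir``."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "gsa": os.path.join(outdir, "gsa.tsv"),
        "degs": os.path.join(outdir, "degs.json"),
        "manifest": os.path.join(outdir, "manifest.json"),
    }
    write_gsa(results.gsa, paths["gsa"])
    write_degs(results.deg, paths["degs"])
    write_manifest(results.config, paths["manifest"])
    return paths
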