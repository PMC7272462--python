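"""Reading and writing the pipeline's text formats.

Matrices are plain whitespace/tab-delimited text (one file per subject, n
rows by n columns); cohort metadata is CSV; parcellation labels are TSV
(index, name, hemisphere); networks can be exported to GraphML; configs and
summaries are YAML/JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .build import WeightedNetwork
from .cohort import Cohort, make_labels

METADATA_COLUMNS = [
    "subject_id", "group", "gcs", "age", "time_since_injury", "rpm_pre", "rpm_post",
]


def write_matrix(matrix: np.ndarray, path: str | Path) -> None:
    matrix = np.asarray(matrix)
    fmt = "%d" if np.issubdtype(matrix.dtype, np.integer) else "%.12g"
    np.savetxt(path, matrix, fmt=fmt, delimiter="\t")


def read_matrix(path: str | Path) -> np.ndarray:
    return np.loadtxt(path)


def write_labels(labels: list[str], path: str | Path) -> None:
    rows = []
    for i, name in enumerate(labels):
        hemi = name.rsplit("_", 1)[-1] if name.rsplit("_", 1)[-1] in ("L", "R") else ""
        rows.append({"index": i, "name": name, "hemisphere": hemi})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_labels(path: str | Path) -> list[str]:
    df = pd.read_csv(path, sep="\t")
    return df.sort_values("index")["name"].astype(str).tolist()


def write_metadata(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def cohort_metadata_frame(cohort: Cohort) -> pd.DataFrame:
    rows = [
        {
            "subject_id": s.id,
            "group": s.group,
            "gcs": s.gcs,
            "age": round(s.age, 3),
            "time_since_injury": None if s.time_since_injury is None else round(s.time_since_injury, 3),
            "rpm_pre": None if s.rpm_pre is None else round(s.rpm_pre, 3),
            "rpm_post": None if s.rpm_post is None else round(s.rpm_post, 3),
        }
        for s in cohort.subjects
    ]
    return pd.DataFrame(rows, columns=METADATA_COLUMNS)


def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Write a cohort to disk: per-subject matrices, metadata, labels, spec.

    Layout: ``matrices/<subject_id>.tsv``, ``metadata.csv``, ``labels.tsv``,
    ``template.tsv`` and ``cohort_spec.yaml`` (seeds included).
    """
    outdir = Path(outdir)
    (outdir / "matrices").mkdir(parents=True, exist_ok=True)
    for s in cohort.subjects:
        write_matrix(s.matrix, outdir / "matrices" / f"{s.id}.tsv")
    write_matrix(cohort.template, outdir / "template.tsv")
    write_metadata(cohort_metadata_frame(cohort), outdir / "metadata.csv")
    write_labels(make_labels(cohort.spec.n_nodes), outdir / "labels.tsv")
    spec_dict = cohort.spec.to_dict()
    spec_dict["cognition_region_used"] = cohort.cognition_region
    with open(outdir / "cohort_spec.yaml", "w") as fh:
        yaml.safe_dump(spec_dict, fh, sort_keys=True)
    return outdir


def read_cohort_dir(indir: str | Path) -> tuple[dict[str, np.ndarray], pd.DataFrame, list[str]]:
    """Load (matrices by subject id, metadata frame, labels) from a cohort dir."""
    indir = Path(indir)
    meta = read_metadata(indir / "metadata.csv")
    matrices = {
        sid: read_matrix(indir / "matrices" / f"{sid}.tsv")
        for sid in meta["subject_id"].astype(str)
    }
    labels_path = indir / "labels.tsv"
    if labels_path.exists():
        labels = read_labels(labels_path)
    else:
        n = next(iter(matrices.values())).shape[0]
        labels = make_labels(n)
    return matrices, meta, labels


def export_graphml(network: WeightedNetwork, path: str | Path) -> None:
    """Export a weighted network as GraphML (edge attribute 'weight')."""
    g = nx.Graph()
    for i, label in enumerate(network.node_labels):
        g.add_node(i, label=label)
    n = network.n_nodes
    for i in range(n):
        for j in range(i + 1, n):
            w = float(network.weights[i, j])
            if w > 0:
                g.add_edge(i, j, weight=w)
    nx.write_graphml(g, path)


def write_json(obj: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"cannot serialize {type(obj)}")
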