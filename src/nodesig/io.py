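"""Readers and writers for the plain-text formats used across the pipeline.

Quantitation tables are TSV with features as rows and samples as columns;
the first column holds the feature id and empty cells mark missing values.
Targeted transition reports are long-format CSV with one row per
(run, peptide, isotope label, transition).
"""

from __future__ import annotations

import json
from collections import defaultdict
from pathlib import Path
from typing import Mapping

import pandas as pd

POSITIVE = "pos"
NEGATIVE = "neg"

_LABEL_ALIASES = {
    "pos": POSITIVE,
    "positive": POSITIVE,
    "pn+": POSITIVE,
    "n+": POSITIVE,
    "1": POSITIVE,
    "neg": NEGATIVE,
    "negative": NEGATIVE,
    "pn0": NEGATIVE,
    "n0": NEGATIVE,
    "0": NEGATIVE,
}


def read_quant_table(path: str | Path) -> pd.DataFrame:
    """Read a feature x sample TSV; empty cells become NaN."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "feature_id"
    if df.index.has_duplicates:
        raise ValueError("duplicate feature ids in quant table")
    if df.columns.has_duplicates:
        raise ValueError("duplicate sample ids in quant table")
    return df.astype(float)


def write_quant_table(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", na_rep="")


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (sample_id, group) into a labels mapping.

    Group values are normalized to ``"pos"``/``"neg"``; common aliases such
    as pN+/pN0 are accepted.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("labels file needs at least two columns")
    labels: dict[str, str] = {}
    for sample, group in zip(df.iloc[:, 0], df.iloc[:, 1]):
        key = str(group).strip().lower()
        if key not in _LABEL_ALIASES:
            raise ValueError(f"unrecognized group label {group!r} for sample {sample!r}")
        labels[str(sample)] = _LABEL_ALIASES[key]
    return labels


def write_labels(labels: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(labels), "group": [labels[s] for s in labels]}
    ).to_csv(path, sep="\t", index=False)


def write_truth(truth, path: str | Path) -> None:
    """Serialize a GroundTruth record as JSON."""
    payload = {
        "true_differential": dict(truth.true_differential),
        "informative_variables": sorted(truth.informative_variables),
        "emt_shifts": dict(truth.emt_shifts),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_truth(path: str | Path):
    from .simulate import GroundTruth

    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        true_differential={k: int(v) for k, v in payload["true_differential"].items()},
        informative_variables=frozenset(payload["informative_variables"]),
        emt_shifts={k: float(v) for k, v in payload["emt_shifts"].items()},
    )


def write_transitions(runs, path: str | Path) -> None:
    """Write TransitionSet records as long CSV (run_id, peptide,
    isotope_label, transition_id, area)."""
    rows = []
    for ts in runs:
        for label, areas in (
            ("light", ts.light_areas),
            ("heavy", ts.heavy_areas),
            ("library", ts.library_intensities),
        ):
            for tid, area in zip(ts.transition_ids, areas):
                rows.append((ts.run_id, ts.peptide_id, label, tid, float(area)))
    pd.DataFrame(
        rows, columns=["run_id", "peptide", "isotope_label", "transition_id", "area"]
    ).to_csv(path, index=False)


def read_transitions(path: str | Path):
    from .targeted_qc import TransitionSet

    df = pd.read_csv(path, dtype={"run_id": str, "peptide": str, "transition_id": str})
    required = {"run_id", "peptide", "isotope_label", "transition_id", "area"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"transition report missing columns: {sorted(missing)}")
    runs = []
    for (run_id, peptide), sub in df.groupby(["run_id", "peptide"], sort=False):
        channels: dict[str, dict[str, float]] = defaultdict(dict)
        for _, row in sub.iterrows():
            channels[row["isotope_label"]][row["transition_id"]] = float(row["area"])
        tids = sorted(channels.get("light", channels.get("heavy", {})).keys())
        runs.append(
            TransitionSet(
                run_id=run_id,
                peptide_id=peptide,
                transition_ids=tuple(tids),
                light_areas=tuple(channels.get("light", {}).get(t, 0.0) for t in tids),
                heavy_areas=tuple(channels.get("heavy", {}).get(t, 0.0) for t in tids),
                library_intensities=tuple(
                    channels.get("library", {}).get(t, 0.0) for t in tids
                ),
            )
        )
    return runs
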