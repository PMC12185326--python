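"""Plain-text readers and writers for panels, moments and derived tables.

The moments file is self-describing delimited text: `#`-prefixed header
lines carry the feature list, wave count, sample size and stacking
convention, followed by the mean row and the covariance block.  Published
covariance matrices stacked feature-major can be ingested with
`order="feature_major"`, which permutes them into the package's wave-major
convention.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import PanelMoments
from .simulate import PanelData

__all__ = [
    "write_panel",
    "read_panel",
    "write_moments",
    "read_moments",
    "write_edge_list",
    "write_centrality",
    "write_model_json",
    "read_model_json",
]


def write_panel(panel: PanelData, path) -> None:
    """Long-format delimited text, one row per individual-wave."""
    df = panel.df.copy()
    df.attrs = {}
    df.to_csv(path, index=False)


def read_panel(path, n_waves: int | None = None) -> PanelData:
    df = pd.read_csv(path)
    features = [c for c in df.columns if c.startswith("f_")]
    if n_waves is None:
        n_waves = int(df["wave"].max())
    return PanelData(df, features, n_waves)


def _stack_permutation(p: int, T: int) -> np.ndarray:
    """Index map from feature-major (all waves of feature 1, ...) stacking
    into wave-major stacking."""
    idx = np.empty(p * T, dtype=int)
    for t in range(T):
        for k in range(p):
            idx[t * p + k] = k * T + t
    return idx


def write_moments(moments: PanelMoments, path) -> None:
    lines = [
        f"#features={','.join(moments.feature_order)}",
        f"#waves={moments.n_waves}",
        f"#n={moments.n}",
        "#order=wave_major",
        "\t".join(repr(float(x)) for x in moments.mean),
    ]
    for row in moments.cov:
        lines.append("\t".join(repr(float(x)) for x in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_moments(path, order: str | None = None) -> PanelMoments:
    """Read a moments file; `order` overrides the header's stacking tag."""
    header: dict[str, str] = {}
    rows: list[list[float]] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        if line.startswith("#"):
            key, _, val = line[1:].partition("=")
            header[key.strip()] = val.strip()
        else:
            rows.append([float(x) for x in line.split("\t")])
    features = header["features"].split(",")
    T = int(header["waves"])
    n = int(header["n"])
    file_order = order or header.get("order", "wave_major")
    mean = np.asarray(rows[0])
    cov = np.asarray(rows[1:])
    p = len(features)
    if mean.shape != (p * T,) or cov.shape != (p * T, p * T):
        raise ValueError(
            f"moments file dimensions inconsistent with p*T = {p * T}"
        )
    if file_order == "feature_major":
        perm = _stack_permutation(p, T)
        mean = mean[perm]
        cov = cov[np.ix_(perm, perm)]
    elif file_order != "wave_major":
        raise ValueError(f"unknown stacking order {file_order!r}")
    return PanelMoments(mean=mean, cov=cov, n=n, feature_order=features, n_waves=T)


def write_edge_list(rows, path) -> None:
    """TSV: source, target, weight, class."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\tweight\tclass\n")
        for s, t, w, c in rows:
            fh.write(f"{s}\t{t}\t{w:.6g}\t{c}\n")


def write_centrality(table, path) -> None:
    table.as_frame().to_csv(path, sep="\t", index=False)


def write_model_json(results, path) -> None:
    Path(path).write_text(json.dumps(results.as_dict(), indent=2) + "\n")


def read_model_json(path) -> dict:
    return json.loads(Path(path).read_text())
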