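"""Round-trip file formats for time series, hyperedge sets, scores, fits.

Text formats only, all deterministic (sorted) so identical runs produce
byte-identical files:

* time series: CSV (header row of variable names, first column ``t`` when
  times are present) or an ``.npz`` container holding X, t, Xdot, base point,
  series lengths and the generating config as JSON metadata;
* directed scores: TSV ``target<TAB>src[,src,...]<TAB>score``;
* ROC: TSV ``epsilon<TAB>tpr<TAB>fpr`` plus a JSON summary;
* sparse fits: JSON with exponent vectors and coefficients.
"""

from __future__ import annotations

import json
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .dynamics import TimeSeries
from .evaluation import ContributionResult, ROCCurve
from .hypergraphs import DirectedHyperedge
from .inference import DirectedScores
from .sindy import MonomialLibrary, SparseFit

__all__ = [
    "write_timeseries_csv", "read_timeseries_csv",
    "write_timeseries_npz", "read_timeseries_npz",
    "write_scores", "read_scores",
    "write_roc", "roc_summary", "write_contributions",
    "write_fit_json", "read_fit_json",
]


def write_timeseries_csv(path, ts: TimeSeries) -> None:
    cols = {}
    if ts.t is not None:
        cols["t"] = ts.t
    for i in range(ts.n_vars):
        cols[f"x{i}"] = ts.X[:, i]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_timeseries_csv(path, base_point=None) -> TimeSeries:
    df = pd.read_csv(path)
    t = df.pop("t").to_numpy() if "t" in df.columns else None
    return TimeSeries(X=df.to_numpy(dtype=float), t=t, base_point=base_point)


def write_timeseries_npz(path, ts: TimeSeries, config: Optional[dict] = None) -> None:
    payload = {"X": ts.X, "series_lengths": np.array(ts.series_lengths)}
    if ts.t is not None:
        payload["t"] = ts.t
    if ts.Xdot is not None:
        payload["Xdot"] = ts.Xdot
    if ts.base_point is not None:
        payload["base_point"] = ts.base_point
    payload["config_json"] = np.array(json.dumps(config or {}, sort_keys=True))
    np.savez_compressed(path, **payload)


def read_timeseries_npz(path) -> TimeSeries:
    with np.load(path, allow_pickle=False) as z:
        return TimeSeries(
            X=z["X"],
            t=z["t"] if "t" in z else None,
            Xdot=z["Xdot"] if "Xdot" in z else None,
            base_point=z["base_point"] if "base_point" in z else None,
            series_lengths=z["series_lengths"].tolist(),
        )


def _edge_key(c: DirectedHyperedge):
    return (c.order, c.target, sorted(c.sources))


def write_scores(path, scores: DirectedScores) -> None:
    with open(path, "w") as fh:
        for c in sorted(scores.scores, key=_edge_key):
            srcs = ",".join(str(v) for v in sorted(c.sources))
            fh.write(f"{c.target}\t{srcs}\t{scores.scores[c]!r}\n")


def read_scores(path) -> DirectedScores:
    out = DirectedScores()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tgt, srcs, val = line.split("\t")
            out.add(DirectedHyperedge(int(tgt),
                                      frozenset(int(v) for v in srcs.split(","))),
                    float(val))
    return out


def write_roc(path_tsv, curve: ROCCurve) -> None:
    with open(path_tsv, "w") as fh:
        fh.write("epsilon\ttpr\tfpr\n")
        for e, t, f in zip(curve.thresholds, curve.tpr, curve.fpr):
            fh.write(f"{e!r}\t{t!r}\t{f!r}\n")


def roc_summary(curve: ROCCurve, n_truth: int, n_candidates: int) -> Dict:
    tpr_end, fpr_end = curve.endpoint()
    return {
        "auc": curve.auc,
        "truncated": curve.truncated,
        "n_truth": n_truth,
        "n_candidates": n_candidates,
        "endpoint_tpr": tpr_end,
        "endpoint_fpr": fpr_end,
    }


def write_contributions(path_tsv, res: ContributionResult) -> None:
    """TSV: epsilon, series, t_index, rho2[, rho3[, rho4]]."""
    cols = "\t".join(f"rho{o}" for o in res.orders)
    starts = np.cumsum([0] + list(res.series_lengths))
    with open(path_tsv, "w") as fh:
        fh.write(f"epsilon\tseries\tt_index\t{cols}\n")
        for ei, eps in enumerate(res.epsilons):
            for si in range(len(res.series_lengths)):
                for k in range(starts[si], starts[si + 1]):
                    vals = "\t".join(repr(float(v)) for v in res.rho[ei, k])
                    fh.write(f"{eps!r}\t{si}\t{k - starts[si]}\t{vals}\n")


def write_fit_json(path, fit: SparseFit, lib: MonomialLibrary,
                   config: Optional[dict] = None) -> None:
    doc = {
        "n_vars": lib.n_vars,
        "max_degree": lib.max_degree,
        "exponents": lib.exponents.tolist(),
        "fit": fit.to_dict(),
        "config": config or {},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True)


def read_fit_json(path):
    with open(path) as fh:
        doc = json.load(fh)
    lib = MonomialLibrary(doc["n_vars"], doc["max_degree"],
                          np.array(doc["exponents"], dtype=int))
    f = doc["fit"]
    fit = SparseFit(
        coefficients=np.array(f["coefficients"]),
        support=np.array(f["support"], dtype=int),
        residual=f["residual"],
        n_iterations=f["n_iterations"],
        scaled_coefficients=np.array(f["scaled_coefficients"]),
    )
    return fit, lib, doc["config"]
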