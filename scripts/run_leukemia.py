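#!/usr/bin/env python
"""Optional real-data pipeline for a Golub-style leukemia expression table.

The 7129-gene x 72-sample acute leukemia dataset is not redistributed here;
download it separately and point this script at a delimited text file with
genes in rows (gene identifiers in the first column, one column per
sample). The script applies the standard preprocessing (clamp to
[100, 16000]; drop genes with max/min <= 5 or max-min <= 500; keep the 300
most variable genes; standardize) and runs the AWE grid-search fit.

    python scripts/run_leukemia.py --input golub.tsv --out-dir leukemia_out
"""

import argparse
import json
import pathlib

import pandas as pd

from tmixnet.data import load_expression, preprocess_leukemia
from tmixnet.network import identify_biomarkers, networks_from_model
from tmixnet.search import AWESearch


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--input", required=True)
    ap.add_argument("--orientation", default="genes", choices=["genes", "samples"])
    ap.add_argument("--top-k", type=int, default=300)
    ap.add_argument("--k-grid", default="2,3,4,5")
    ap.add_argument("--lambda1-grid", default="3,6")
    ap.add_argument("--lambda2-grid", default="30,45,60")
    ap.add_argument("--restarts", type=int, default=5)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--edge-threshold", type=float, default=0.01)
    ap.add_argument("--out-dir", required=True)
    args = ap.parse_args()

    raw = load_expression(args.input, orientation=args.orientation)
    X = preprocess_leukemia(raw, top_k=args.top_k)
    print(f"{raw.p} genes -> {X.p} after preprocessing; {X.n} samples")

    search = AWESearch(
        K_grid=tuple(int(k) for k in args.k_grid.split(",")),
        lambda1_grid=tuple(float(v) for v in args.lambda1_grid.split(",")),
        lambda2_grid=tuple(float(v) for v in args.lambda2_grid.split(",")),
        family="pmt-uc", n_restarts=args.restarts, nu_bounds=(3.0, 30.0),
        random_state=args.seed,
    )
    search.fit(X)
    model = search.best_estimator_

    out = pathlib.Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"sample": list(X.sample_ids), "cluster": model.labels_}).to_csv(
        out / "labels.csv", index=False)
    search.results_.to_csv(out / "selection_table.csv", index=False)
    nets = networks_from_model(model, threshold=args.edge_threshold)
    pd.concat([n.to_edgelist() for n in nets], ignore_index=True).to_csv(
        out / "edges.tsv", sep="\t", index=False)
    identify_biomarkers(model, nets).to_frame().to_csv(
        out / "biomarkers.csv", index=False)
    (out / "fit_summary.json").write_text(json.dumps(
        dict(selected=search.best_params_, awe=model.awe_,
             effective_params=model.effective_params_), indent=2))
    print("selected:", search.best_params_)


if __name__ == "__main__":
    main()
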