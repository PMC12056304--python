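#!/usr/bin/env python
"""Plaque-level diameter–distance correlation structure across arms.

Pools the per-plaque records emitted by 02_run_pipeline.py, computes the
Pearson correlation of maximum diameter against nearest-vessel distance per
treatment arm (with and without 0-µm contact plaques), and compares arms
with the one-tailed Fisher Z test for independent correlations. Writes
results/correlations.csv and results/fisher_z.csv."""

import os

import pandas as pd

from plaquemetrics import stats, vascular
from plaquemetrics.io import read_table, write_table

PIPELINE_OUT = os.path.join("results", "pipeline")


def main() -> None:
    path = os.path.join(PIPELINE_OUT, "plaque_vessel.csv")
    if not os.path.exists(path):
        raise SystemExit("run analysis/02_run_pipeline.py first (missing plaque_vessel.csv)")
    records = read_table(path)
    rows, fz_rows = [], []
    rs: dict[str, tuple[float, int]] = {}
    for group, sub in records.groupby("group"):
        for include, label in ((True, "all"), (False, "excluding_contacts")):
            try:
                r, n, p = vascular.diameter_distance_correlation(sub, include_contacts=include)
            except Exception as exc:
                print(f"{group} ({label}): correlation unavailable ({exc})")
                continue
            rows.append(dict(group=group, mode=label, r=r, n=n, p=p))
            if include:
                rs[group] = (r, n)
            print(f"{group:12s} ({label:18s}) r = {r:+.3f}  n = {n:4d}  p = {p:.3g}")
    for g1, g2 in [("facilitator", "control"), ("facilitator", "inhibitor"), ("control", "inhibitor")]:
        if g1 in rs and g2 in rs:
            (r1, n1), (r2, n2) = rs[g1], rs[g2]
            fz = stats.fisher_z_independent(r1, n1, r2, n2, tail="greater")
            fz_rows.append(
                dict(group_1=g1, group_2=g2, r1=r1, n1=n1, r2=r2, n2=n2, z=fz.z, p=fz.p)
            )
            print(f"Fisher Z {g1} vs {g2}: Z = {fz.z:+.3f}, one-tailed p = {fz.p:.4f}")
    write_table(pd.DataFrame(rows), os.path.join("results", "correlations.csv"))
    write_table(pd.DataFrame(fz_rows), os.path.join("results", "fisher_z.csv"))


if __name__ == "__main__":
    main()
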