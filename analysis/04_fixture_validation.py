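#!/usr/bin/env python
"""Measurement-calibration figures: box-counting fits and overlap recovery.

Recomputes the fractal-dimension fixtures (line, Sierpinski triangle, filled
square) with their log–log box-count fits, and the constructed-overlap
recovery curve of the colocalization stage, writing
results/fd_boxcount.png, results/overlap_recovery.png and
results/validation_summary.csv."""

import os

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from plaquemetrics import colocalization as coloc
from plaquemetrics import morphometry, synthetic
from plaquemetrics.io import write_table

OUT = "results"
SEED = 13


def boxcount_curve(mask):
    rows, cols = np.nonzero(mask)
    crop = mask[rows.min() : rows.max() + 1, cols.min() : cols.max() + 1]
    side = 2 ** int(np.ceil(np.log2(max(crop.shape))))
    padded = np.zeros((side, side), dtype=bool)
    padded[: crop.shape[0], : crop.shape[1]] = crop
    sizes = [2**k for k in range(1, int(np.log2(side)))]
    counts = [
        int(padded.reshape(side // s, s, side // s, s).any(axis=(1, 3)).sum())
        for s in sizes
    ]
    return np.asarray(sizes), np.asarray(counts)


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    rows = []

    fixtures = {
        "line (FD 1)": synthetic.generate_fractal_mask("line", 128),
        "Sierpinski triangle (FD 1.585)": synthetic.generate_fractal_mask(
            "sierpinski_triangle", 7
        ),
        "filled square (FD 2)": synthetic.generate_fractal_mask("filled_square", 64),
    }
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, mask in fixtures.items():
        fd = morphometry.box_counting_fd(mask)
        s, n = boxcount_curve(mask)
        ax.plot(np.log(1 / s), np.log(n), "o-", label=f"{label}: slope {fd:.3f}")
        rows.append(dict(check="box_counting_fd", fixture=label, value=fd))
        print(f"{label:34s} measured FD = {fd:.4f}")
    ax.set_xlabel("log(1 / box size)")
    ax.set_ylabel("log N(boxes)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(os.path.join(OUT, "fd_boxcount.png"), dpi=150)

    spec = synthetic.SceneSpec(n_plaques=20, seed=SEED, noise_sd=0.0)
    scene, _ = synthetic.generate_scene(spec)
    rhos = [0.0, 0.25, 0.5, 0.75, 1.0]
    measured = []
    for rho in rhos:
        img = synthetic.render_fluorescence(scene, overlap=rho, noise_sd=0.0)
        r = coloc.overlap_coefficient(
            img.channel("ab40").astype(float), img.channel("ab42").astype(float), 90, 90
        )
        measured.append(r)
        rows.append(dict(check="overlap_recovery", fixture=f"rho={rho}", value=r))
        print(f"constructed overlap {rho:.2f} -> measured {r:.4f}")
    fig2, ax2 = plt.subplots(figsize=(4, 4))
    ax2.plot(rhos, measured, "o-")
    ax2.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax2.set_xlabel("constructed overlap")
    ax2.set_ylabel("measured Manders coefficient")
    fig2.tight_layout()
    fig2.savefig(os.path.join(OUT, "overlap_recovery.png"), dpi=150)

    write_table(pd.DataFrame(rows), os.path.join(OUT, "validation_summary.csv"))
    print(f"figures and table written to {OUT}/")


if __name__ == "__main__":
    main()
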