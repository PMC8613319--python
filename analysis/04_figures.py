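#!/usr/bin/env python
"""Summary figures: category counts and per-category metric profiles.

Writes results/figures/category_counts.png and metric_profiles.png from the
study outputs of 01.  The profiles mirror the standard presentation of
per-category image-quality metrics across the four reconstructions, with
the no-prosthesis reference drawn as a horizontal line.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from thamar.io import read_measurements_csv
from thamar.metrics import DEFAULT_REFERENCE_VALUES, RECONSTRUCTION_KEYS

ROOT = Path(__file__).resolve().parents[1]
STUDY = ROOT / "results" / "study"
FIG = ROOT / "results" / "figures"


def main() -> None:
    path = STUDY / "measurements.csv"
    if not path.exists():
        raise SystemExit("run analysis/01_simulate_study.py first")
    FIG.mkdir(parents=True, exist_ok=True)
    meas = read_measurements_csv(path)

    counts = pd.read_csv(STUDY / "category_counts.csv").set_index("config")
    ax = counts[["unaffected", "mild", "severe"]].plot.bar(
        color=["#3a923a", "#e1a915", "#c23b3b"], rot=0
    )
    ax.set_ylabel("pellets")
    ax.set_title("Pellet severity per prosthesis configuration")
    plt.tight_layout()
    plt.savefig(FIG / "category_counts.png", dpi=150)
    plt.close()

    pellets = meas[(meas.label != "BG") & (meas.config != "none")]
    metrics = [("mean_hu", "CT value (HU)"), ("cnr", "CNR"),
               ("snr", "SNR"), ("noise_hu", "noise (HU)")]
    fig, axes = plt.subplots(2, 2, figsize=(10, 7), sharex=True)
    for (metric, label), ax in zip(metrics, axes.ravel()):
        for category, color in (("unaffected", "#3a923a"), ("mild", "#e1a915"),
                                ("severe", "#c23b3b")):
            sub = pellets[pellets.category == category]
            means = sub.groupby("recon_key")[metric].mean().reindex(
                list(RECONSTRUCTION_KEYS)
            )
            ax.plot(range(4), means.values, "o-", color=color, label=category)
        for family, style in (("conventional", "--"), ("vmi130", ":")):
            ax.axhline(
                DEFAULT_REFERENCE_VALUES[family][metric], ls=style, c="gray", lw=0.8
            )
        ax.set_title(label)
        ax.set_xticks(range(4), ["conv", "conv+MAR", "VMI", "VMI+MAR"], rotation=20)
    axes[0, 0].legend()
    fig.suptitle("Per-category image quality across reconstructions\n"
                 "(gray lines: no-prosthesis references, conventional/VMI)")
    plt.tight_layout()
    plt.savefig(FIG / "metric_profiles.png", dpi=150)
    plt.close()
    print(f"figures written to {FIG}")


if __name__ == "__main__":
    main()
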