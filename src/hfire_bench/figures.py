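"""Demo figure regeneration: synthetic analogues of the bench summary plots.

These are demonstrations of the pipeline's outputs (resistance vs applied
distance-normalized voltage by delay; conductivity vs field by pulse width),
not acceptance surfaces.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_resistance_by_delay(table: pd.DataFrame, out_path: str | Path) -> Path:
    """One panel per pulse width: mean R vs level, one line per delay."""
    pws = sorted(table["pulse_width_us"].unique())
    fig, axes = plt.subplots(1, len(pws), figsize=(4 * len(pws), 3.2), squeeze=False)
    for ax, pw in zip(axes[0], pws):
        sub = table[table["pulse_width_us"] == pw]
        for (d1, d2), grp in sub.groupby(["d1_us", "d2_us"]):
            agg = grp.groupby("level_v_per_cm")["R_ohm"].agg(["mean", "sem"])
            ax.errorbar(agg.index, agg["mean"], yerr=agg["sem"], label=f"d={d1:g}/{d2:g} µs")
        ax.set_xlabel("applied field (V/cm)")
        ax.set_ylabel("resistance (Ω)")
        ax.set_title(f"{pw:g} µs pulses")
        ax.legend(fontsize=7)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path


def plot_conductivity_curves(curves: dict[str, pd.DataFrame], out_path: str | Path) -> Path:
    """Conductivity vs applied field, one line per labelled curve."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for label, df in curves.items():
        ax.plot(df["level_v_per_cm"], df["sigma_s_per_m"], marker="o", label=label)
    ax.set_xlabel("applied field (V/cm)")
    ax.set_ylabel("conductivity (S/m)")
    ax.legend()
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
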