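"""Render risk-curve panels and Sankey-style flow diagrams from a run dir.

Presentation only — nothing here is computed; it draws what the pipeline
wrote.  Usage:  python scripts/plot_figures.py --run run --out run/figures
"""

from __future__ import annotations

import argparse
import glob
import json
import os

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

SEX_COLOURS = {"female": "tab:red", "male": "tab:blue"}


def plot_risk_curves(run: str, out: str) -> None:
    rc = pd.read_csv(os.path.join(run, "risk_curves.csv"))
    types = sorted(rc["move_type"].unique())
    fig, axes = plt.subplots(2, 2, figsize=(10, 7), sharex=True)
    for ax, mt in zip(axes.ravel(), types):
        for sex, colour in SEX_COLOURS.items():
            sub = rc[(rc["move_type"] == mt) & (rc["sex"] == sex)]
            ax.plot(sub["age"], sub["percent"], color=colour, label=sex)
            ax.fill_between(sub["age"], sub["ci_lo"], sub["ci_hi"],
                            color=colour, alpha=0.2)
        ax.set_title(mt.replace("_", " "))
        ax.set_xlabel("age (years)")
        ax.set_ylabel("% moving per quarter")
    axes[0, 0].legend()
    fig.tight_layout()
    fig.savefig(os.path.join(out, "risk_curves.png"), dpi=120)
    plt.close(fig)


def plot_sankey(path: str, out: str) -> None:
    """Two-column flow diagram (sending left, receiving right)."""
    with open(path) as fh:
        js = json.load(fh)
    nodes = [n["name"] for n in js["nodes"]]
    send = [n for n in nodes if n.startswith("sending:")]
    recv = [n for n in nodes if n.startswith("receiving:")]
    ypos = {}
    for col, names in ((0, send), (1, recv)):
        for i, n in enumerate(names):
            ypos[n] = (col, i / max(len(names) - 1, 1))
    fig, ax = plt.subplots(figsize=(8, 6))
    total = sum(l["value"] for l in js["links"]) or 1
    for link in js["links"]:
        a, b = nodes[link["source"]], nodes[link["target"]]
        (x0, y0), (x1, y1) = ypos[a], ypos[b]
        ax.plot([x0 + 0.05, x1 - 0.05], [y0, y1], color="grey",
                alpha=0.35, lw=1 + 20 * link["value"] / total)
    for n, (x, y) in ypos.items():
        ax.text(x, y, n.split(":", 1)[1], ha="right" if x == 0 else "left",
                va="center", fontsize=8)
    ax.set_xlim(-0.4, 1.4)
    ax.axis("off")
    stem = os.path.splitext(os.path.basename(path))[0]
    ax.set_title(stem.replace("sankey_", "").replace("_", " "))
    fig.tight_layout()
    fig.savefig(os.path.join(out, stem + ".png"), dpi=120)
    plt.close(fig)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--run", default="run")
    ap.add_argument("--out", default=None)
    args = ap.parse_args()
    out = args.out or os.path.join(args.run, "figures")
    os.makedirs(out, exist_ok=True)
    if os.path.exists(os.path.join(args.run, "risk_curves.csv")):
        plot_risk_curves(args.run, out)
    for path in sorted(glob.glob(os.path.join(args.run, "sankey_*.json"))):
        plot_sankey(path, out)
    print(f"figures written to {out}")


if __name__ == "__main__":
    main()
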