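"""Waterfall plot rendering (one colored segment per motif per read)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

#: Motif colors: pure GAA in green, interruption motifs in warm colors.
MOTIF_COLORS = {
    "GAA": "#2ca02c",
    "GCAGAA": "#d62728",
    "GCAGAAGAA": "#ff7f0e",
    "GCAGCAGAA": "#9467bd",
    "GCAGAAGAAGAA": "#8c564b",
    "GCAGAAGAAGAAGAA": "#e377c2",
    "NOISE": "#bbbbbb",
}


def plot_waterfall(matrix: pd.DataFrame, path: str | Path, title: str = "") -> None:
    """Render a waterfall matrix (see ``waterfall_matrix``) to an image.

    Reads appear top to bottom by ascending tract length; x is the tract
    coordinate in nt.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    read_order = list(dict.fromkeys(matrix["read_id"]))
    y_of = {rid: i for i, rid in enumerate(read_order)}
    fig, ax = plt.subplots(
        figsize=(10, max(2, 0.12 * len(read_order) + 1))
    )
    for row in matrix.itertuples():
        ax.hlines(
            y_of[row.read_id],
            row.start,
            row.end,
            colors=MOTIF_COLORS.get(row.motif, "#000000"),
            linewidth=3,
        )
    ax.set_xlabel("tract position (nt)")
    ax.set_ylabel("reads (sorted by tract length)")
    ax.set_yticks([])
    ax.invert_yaxis()
    if title:
        ax.set_title(title)
    handles = [
        plt.Line2D([0], [0], color=color, lw=4, label=motif)
        for motif, color in MOTIF_COLORS.items()
        if motif in set(matrix["motif"])
    ]
    ax.legend(handles=handles, loc="lower right", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
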