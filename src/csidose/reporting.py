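"""Rendering of technique-comparison matrices: long CSV and optional heat maps."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import ValidationError
from .workflow import TechniqueComparison


def render_matrices(
    comparison: TechniqueComparison,
    outdir: str | Path,
    images: bool = False,
) -> dict[str, Path]:
    """Write comparison matrices as CSVs (and, optionally, PNG heat maps).

    Wide CSVs keep the input organ order; the long CSV is
    ``organ,technique,metric,value`` and round-trips numerically through
    ``pandas.read_csv``.
    """
    if comparison.eud_gy.empty:
        raise ValidationError("nothing to render: empty comparison matrices")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, df in (
        ("eud_matrix", comparison.eud_gy),
        ("ntcp_matrix", comparison.ntcp_pct),
        ("delta_eud_matrix", comparison.delta_eud_gy),
        ("ratio_eud_matrix", comparison.ratio_eud),
    ):
        p = outdir / f"{name}.csv"
        df.to_csv(p)
        paths[name] = p
    p = outdir / "comparison_long.csv"
    comparison.to_long_frame().to_csv(p, index=False)
    paths["comparison_long"] = p
    if images:
        paths.update(_render_heatmaps(comparison, outdir))
    return paths


def _render_heatmaps(comparison: TechniqueComparison, outdir: Path) -> dict[str, Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths: dict[str, Path] = {}
    for name, df, label in (
        ("eud_heatmap", comparison.eud_gy, "EUD (Gy)"),
        ("ntcp_heatmap", comparison.ntcp_pct, "NTCP (%)"),
    ):
        fig, ax = plt.subplots(figsize=(1.8 + 1.2 * df.shape[1], 0.6 + 0.4 * df.shape[0]))
        im = ax.imshow(df.to_numpy(float), aspect="auto", cmap="YlOrRd")
        ax.set_xticks(range(df.shape[1]), df.columns)
        ax.set_yticks(range(df.shape[0]), df.index)
        for i in range(df.shape[0]):
            for j in range(df.shape[1]):
                v = df.iat[i, j]
                if pd.notna(v):
                    ax.text(j, i, f"{v:.1f}", ha="center", va="center", fontsize=8)
        fig.colorbar(im, ax=ax, label=label)
        fig.tight_layout()
        p = outdir / f"{name}.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        paths[name] = p
    return paths
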