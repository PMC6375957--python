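"""Ecological summary: detection counts, enrichment, lifestyle fractions.

The detection matrix cross-tabulates confident RP detections (one per
distinct domain hit kept by the screen) against ecosystem labels.
Enrichment of an RP in an ecosystem is formalized as a two-sided Fisher
exact test on the 2x2 table (this RP in this ecosystem vs all others) with
Benjamini–Hochberg correction across all (RP, ecosystem) pairs; the
published observations are qualitative, so the test and correction are
named in every output header.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .models import ECOSYSTEMS, LifestyleCall, RpDetection
from .pnps import PnpsResult, SelectionSummary, aggregate_selection

log = logging.getLogger(__name__)


def _ecosystem_order(labels: set[str]) -> list[str]:
    fixed = [e for e in ECOSYSTEMS if e in labels]
    extra = sorted(labels - set(ECOSYSTEMS))
    return fixed + extra


def build_detection_matrix(detections: Sequence[RpDetection]) -> pd.DataFrame:
    """RP-by-ecosystem contingency table of detection counts.

    Rows are rp_names (alphabetical), columns ecosystems in canonical
    order; cells count detection events (a contig with two distinct RPs
    contributes twice).
    """
    if not detections:
        return pd.DataFrame(dtype=int)
    rps = sorted({d.rp.rp_name for d in detections})
    ecos = _ecosystem_order({d.ecosystem for d in detections})
    matrix = pd.DataFrame(0, index=rps, columns=ecos, dtype=int)
    for d in detections:
        matrix.loc[d.rp.rp_name, d.ecosystem] += 1
    matrix.index.name = "rp_name"
    return matrix


def enrichment_by_ecosystem(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-(RP, ecosystem) Fisher exact enrichment with BH correction.

    Each test compares the count of one RP in one ecosystem against all
    other RPs and ecosystems (2x2, two-sided).  Odds ratios use the
    Haldane 0.5 correction when any cell is zero.  Returns an empty frame
    with a warning when fewer than two ecosystems are present.
    """
    if matrix.empty or matrix.shape[1] < 2:
        log.warning("enrichment requires >= 2 ecosystems; returning empty result")
        return pd.DataFrame(
            columns=["rp_name", "ecosystem", "odds_ratio", "p_value", "q_value"]
        )
    total = int(matrix.values.sum())
    rows = []
    for rp in matrix.index:
        for eco in matrix.columns:
            a = int(matrix.loc[rp, eco])
            b = int(matrix.loc[rp].sum()) - a
            c = int(matrix[eco].sum()) - a
            d = total - a - b - c
            _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
            if min(a, b, c, d) == 0:
                oddsr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
            else:
                oddsr = (a * d) / (b * c)
            rows.append({"rp_name": rp, "ecosystem": eco,
                         "odds_ratio": oddsr, "p_value": p})
    df = pd.DataFrame(rows)
    df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df


def fraction_with_lifestyle(detections: Sequence[RpDetection],
                            lifestyle_calls: Mapping[str, LifestyleCall],
                            rp_name: Optional[str] = None
                            ) -> tuple[int, int, float]:
    """(n_contigs, n_temperate, fraction) among RP-carrying contigs.

    Restricts to contigs carrying ``rp_name`` when given.  A detection on a
    contig without a lifestyle call is counted as non-temperate (absence of
    evidence) with a warning.
    """
    contig_ids = sorted({
        d.contig_id for d in detections
        if rp_name is None or d.rp.rp_name == rp_name
    })
    n_temperate = 0
    for cid in contig_ids:
        call = lifestyle_calls.get(cid)
        if call is None:
            log.warning("contig %s has detections but no lifestyle call; "
                        "counted as non-temperate", cid)
        elif call.temperate:
            n_temperate += 1
    n_total = len(contig_ids)
    return n_total, n_temperate, (n_temperate / n_total if n_total else 0.0)


def plot_detection_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Stacked per-RP detection bar chart on a log10 y-axis (zero = no bar)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(6, 0.6 * len(matrix)), 4))
    bottom = np.zeros(len(matrix))
    for eco in matrix.columns:
        vals = matrix[eco].to_numpy(dtype=float)
        ax.bar(matrix.index, vals, bottom=bottom, label=eco)
        bottom += vals
    ax.set_yscale("log")
    ax.set_ylabel("detections (log10 scale)")
    ax.set_xlabel("ribosomal protein")
    ax.legend(fontsize=8)
    fig.autofmt_xdate(rotation=45)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def write_report(outdir: str | Path,
                 detections: Sequence[RpDetection],
                 lifestyle_calls: Mapping[str, LifestyleCall],
                 host_predictions: Optional[Mapping] = None,
                 pnps_results: Optional[Sequence[PnpsResult]] = None,
                 make_figure: bool = False) -> SelectionSummary | None:
    """Emit the report directory: detection, enrichment, lifestyle, summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    matrix = build_detection_matrix(detections)
    matrix.to_csv(outdir / "detections_by_ecosystem.tsv", sep="\t")

    enrich = enrichment_by_ecosystem(matrix)
    with open(outdir / "enrichment.tsv", "w") as fh:
        fh.write("# two-sided Fisher exact test per (RP, ecosystem) 2x2 table; "
                 "Benjamini-Hochberg q-values; Haldane 0.5 odds-ratio "
                 "correction for zero cells\n")
        enrich.to_csv(fh, sep="\t", index=False)

    rows = []
    for rp in sorted({d.rp.rp_name for d in detections}) or []:
        n, t, f = fraction_with_lifestyle(detections, lifestyle_calls, rp)
        rows.append({"rp_name": rp, "n_contigs": n, "n_temperate": t,
                     "fraction_temperate": f})
    pd.DataFrame(rows, columns=["rp_name", "n_contigs", "n_temperate",
                                "fraction_temperate"]
                 ).to_csv(outdir / "lifestyle_summary.tsv", sep="\t", index=False)

    summary: dict = {
        "n_detections": len(detections),
        "n_rp_carrier_contigs": len({d.contig_id for d in detections}),
        "n_temperate_contigs": sum(c.temperate for c in lifestyle_calls.values()),
        "n_contigs_with_lifestyle_call": len(lifestyle_calls),
    }
    if host_predictions is not None:
        summary["n_hosts_predicted"] = len(host_predictions)
    sel = None
    if pnps_results is not None:
        sel = aggregate_selection(pnps_results)
        summary["selection"] = {
            "n_genes": sel.n_genes,
            "n_included": sel.n_included,
            "n_ratio_defined": sel.n_ratio_defined,
            "mean_pnps": sel.mean_ratio,
            "frac_pnps_le_0.20": sel.frac_le_threshold,
            "exclusion_counts": sel.exclusion_counts,
        }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)

    if make_figure and not matrix.empty:
        plot_detection_matrix(matrix, outdir / "detections.png")
    return sel
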