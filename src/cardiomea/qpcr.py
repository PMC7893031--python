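"""qPCR relative quantification by the comparative Ct (delta-delta-Ct) method.

Technical replicates are averaged per (sample, gene); the reference Ct of a
sample is the arithmetic mean of its per-gene mean Cts over the chosen
housekeeping genes (equivalent to a geometric mean at the expression
level); dCt = Ct_target - Ct_ref; ddCt is taken against the mean dCt of the
calibrator group; fold change = 2^(-ddCt), i.e. perfect doubling per cycle.

The default housekeeping panel (GAPDH, TBP, EEF1A1) is a standard
cardiomyocyte qPCR reference panel.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_REFERENCE_GENES = ("GAPDH", "TBP", "EEF1A1")

CT_COLUMNS = ["sample", "group", "gene", "replicate", "ct"]


def validate_ct_table(ct: pd.DataFrame) -> None:
    missing = [c for c in CT_COLUMNS if c not in ct.columns]
    if missing:
        raise ValueError(f"Ct table lacks columns {missing}")
    if not ((ct["ct"] > 0) & (ct["ct"] < 45)).all():
        raise ValueError("Ct values must lie in (0, 45)")


def relative_expression(
    ct: pd.DataFrame,
    target_gene: str,
    reference_genes=DEFAULT_REFERENCE_GENES,
    calibrator_group: str = "control",
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Per-sample fold changes of ``target_gene`` and per-group summaries.

    Returns ``(per_sample, group_summary, excluded_samples)``.  A sample is
    excluded (and reported) when it lacks the target gene or every
    reference gene.
    """
    validate_ct_table(ct)
    ref_set = [g for g in reference_genes]
    per_gene = (
        ct.groupby(["sample", "group", "gene"], sort=False)["ct"].mean().reset_index()
    )
    rows = []
    excluded: list[str] = []
    for (sample, group), grp in per_gene.groupby(["sample", "group"], sort=False):
        genes = dict(zip(grp["gene"], grp["ct"]))
        refs = [genes[g] for g in ref_set if g in genes]
        if target_gene not in genes or not refs:
            excluded.append(sample)
            continue
        rows.append(
            {
                "sample": sample,
                "group": group,
                "dct": genes[target_gene] - float(np.mean(refs)),
            }
        )
    per_sample = pd.DataFrame(rows)
    calib = per_sample[per_sample["group"] == calibrator_group]
    if calib.empty:
        raise ValueError(f"no samples in calibrator group {calibrator_group!r}")
    calib_dct = float(calib["dct"].mean())
    per_sample["ddct"] = per_sample["dct"] - calib_dct
    per_sample["fold"] = 2.0 ** (-per_sample["ddct"])
    summary = (
        per_sample.groupby("group", sort=False)["fold"]
        .agg(n="size", mean="mean", sd=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0)
        .reset_index()
    )
    return per_sample, summary, excluded


def synth_ct_table(
    group_folds: dict[str, float],
    n_samples: dict[str, int],
    target_gene: str = "SLC2A1",
    reference_genes=DEFAULT_REFERENCE_GENES,
    n_replicates: int = 3,
    base_dct: float = 8.0,
    group_sd_cycles: float = 0.2,
    replicate_sd_cycles: float = 0.1,
    sample_offset_sd_cycles: float = 0.5,
    rng: np.random.Generator | int | None = 0,
) -> pd.DataFrame:
    """Generate a seeded Ct table with programmed per-group true folds.

    Each sample's true dCt is ``base_dct - log2(group fold)`` plus a small
    inter-sample spread; housekeeping Cts vary per sample by a common RNA
    input offset (which cancels in the ddCt), and every well adds technical
    replicate noise.
    """
    rng = np.random.default_rng(rng)
    hk_base = {g: ct for g, ct in zip(reference_genes, (18.0, 26.0, 20.0, 22.0, 24.0))}
    rows = []
    for group, fold in group_folds.items():
        for i in range(n_samples[group]):
            sample = f"{group}_{i + 1}"
            offset = sample_offset_sd_cycles * rng.standard_normal()
            dct = base_dct - np.log2(fold) + group_sd_cycles * rng.standard_normal()
            ref_mean = float(np.mean([hk_base[g] for g in reference_genes]))
            for gene in reference_genes:
                for rep in range(n_replicates):
                    rows.append(
                        {
                            "sample": sample,
                            "group": group,
                            "gene": gene,
                            "replicate": rep + 1,
                            "ct": hk_base[gene] + offset + replicate_sd_cycles * rng.standard_normal(),
                        }
                    )
            for rep in range(n_replicates):
                rows.append(
                    {
                        "sample": sample,
                        "group": group,
                        "gene": target_gene,
                        "replicate": rep + 1,
                        "ct": ref_mean + offset + dct + replicate_sd_cycles * rng.standard_normal(),
                    }
                )
    return pd.DataFrame(rows)
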