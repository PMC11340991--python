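"""Genic-content classification and enrichment testing of insertion sites.

Each insertion breakpoint is classified as CDS, UTR, intron, or
intergenic (precedence CDS > UTR > intron across overlapping
transcripts).  Observed category proportions are compared against the
genome-wide base-pair fractions with a 2×2 test per category
(in-category vs rest × observed vs expected): Pearson chi-square without
continuity correction, or Fisher's exact test when any expected cell is
below 5.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats as sps

from .genome import CATEGORIES, GenomeModel

__all__ = ["classify_site", "classify_sites", "expected_fractions",
           "enrichment_test"]


def classify_site(chrom: str, pos: int, model: GenomeModel) -> str:
    """Category of one insertion point (raises for out-of-bounds sites)."""
    return model.classify(chrom, pos)


def classify_sites(sites: pd.DataFrame, model: GenomeModel) -> pd.Series:
    return pd.Series(
        [model.classify(c, p) for c, p in zip(sites["chrom"], sites["pos"])],
        index=sites.index, name="category",
    )


def expected_fractions(model: GenomeModel) -> dict[str, float]:
    """Per-category fraction of nuclear base pairs (sums to 1)."""
    return model.category_fractions()


def enrichment_test(
    observed: dict[str, int] | pd.Series,
    model: GenomeModel,
    categories: tuple[str, ...] = CATEGORIES,
) -> pd.DataFrame:
    """Per-category 2×2 enrichment of observed sites vs genomic expectation.

    ``observed`` maps category → site count.  Expected counts are the
    genome base-pair fraction times the total observed sites.  Returns one
    row per category with the observed/expected proportions, the test used,
    its statistic (NaN for Fisher), odds ratio, and p-value.
    """
    obs = {c: int(dict(observed).get(c, 0)) for c in categories}
    total = sum(obs.values())
    if total <= 0:
        raise ValueError("no observed sites")
    frac = expected_fractions(model)
    rows = []
    for cat in categories:
        exp_in = frac[cat] * total
        table = [
            [obs[cat], total - obs[cat]],
            [exp_in, total - exp_in],
        ]
        use_fisher = min(exp_in, total - exp_in) < 5
        if obs[cat] == round(exp_in):
            stat, p, test = 0.0, 1.0, "chi-square"
        elif use_fisher:
            int_table = [[obs[cat], total - obs[cat]],
                         [round(exp_in), total - round(exp_in)]]
            _, p = sps.fisher_exact(int_table)
            stat, test = float("nan"), "fisher"
        else:
            stat, p, _, _ = sps.chi2_contingency(table, correction=False)
            test = "chi-square"
        rows.append(
            dict(category=cat, observed=obs[cat], observed_frac=obs[cat] / total,
                 expected_frac=frac[cat], expected=exp_in, test=test,
                 statistic=stat, p=p)
        )
    return pd.DataFrame(rows)
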