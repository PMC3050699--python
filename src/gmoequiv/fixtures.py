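"""Packaged example data: a four-site maize grain compositional study.

Two small tables summarise the per-analyte results of a comparative field
study of one GM maize variety, its conventional counterpart and 13
commercial reference varieties grown at four sites (the raw plot data are
not public; the tables carry everything the assessment needs):

* ``maize_grain_means.csv`` - geometric means for the three groups and the
  REML variance components (genotype, site, block-within-site, residual)
  on the ln^2 scale, for each of 53 analytes;
* ``maize_grain_contrasts.csv`` - the GMO/counterpart ratio with its 90%
  confidence interval, model-1 sed and Kenward-Roger df, and the
  GMO/reference-mean ratio with its 95% interval, model-2 sed and df.

Fifteen further analytes of the original 68 had (all but at most one)
results below the reporting limit and are not part of the tables.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .assessment import AssessmentConfig, EquivalenceAssessment, assess_from_summary

__all__ = [
    "load_maize_means",
    "load_maize_contrasts",
    "load_maize_summary",
    "assess_maize_example",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("gmoequiv.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_maize_means() -> pd.DataFrame:
    """Geometric means and variance components, one row per analyte."""
    return _read("maize_grain_means.csv")


def load_maize_contrasts() -> pd.DataFrame:
    """Per-analyte contrast summaries (ratios, CIs, seds, dfs)."""
    return _read("maize_grain_contrasts.csv")


def load_maize_summary() -> pd.DataFrame:
    """The two tables merged on analyte (53 rows)."""
    return load_maize_means().merge(load_maize_contrasts(), on="analyte")


def assess_maize_example(
    config: AssessmentConfig | None = None,
) -> list[EquivalenceAssessment]:
    """Re-run the full difference/equivalence assessment from the packaged
    summaries, one :class:`EquivalenceAssessment` per analyte."""
    table = load_maize_summary()
    return [
        assess_from_summary(
            analyte=row.analyte,
            ratio_gc=row.ratio_gc,
            sed_gc1=row.sed_gc1,
            df_gc1=row.df_gc1,
            ratio_gr=row.ratio_gr,
            sed_gr2=row.sed_gr2,
            df_gr2=row.df_gr2,
            var_genotype=row.var_genotype,
            gm_reference=row.gm_reference,
            config=config,
            d_interval=(row.dlow, row.dupp),
            gr_interval=(row.elow, row.eupp),
        )
        for row in table.itertuples(index=False)
    ]
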