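"""Data model, file I/O and preprocessing for comparative field-trial data.

The expected input is a long-format table with one row per plot x analyte,
carrying the site, the block within the site, the genotype label, the
genotype group (``counterpart``, ``gmo`` or ``reference``), the measured
concentration and, optionally, a below-limit-of-reporting flag with the
reporting limit itself.

Preprocessing follows the conventions of comparative compositional
assessment: analytes in which (almost) every result sits below the
reporting limit are dropped, remaining non-detects are replaced by half the
reporting limit, user-identified outliers are removed, and values are
ln-transformed so that multiplicative effects become additive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "COUNTERPART",
    "GMO",
    "REFERENCE",
    "PlotRecord",
    "DesignSummary",
    "PrepConfig",
    "AnalyteDataset",
    "TrialDataError",
    "TrialFormatError",
    "read_trial_table",
    "screen_reporting_limit",
    "substitute_nondetects",
    "finalize_dataset",
    "prepare_analytes",
]

COUNTERPART = "counterpart"
GMO = "gmo"
REFERENCE = "reference"

#: accepted spellings for the three genotype groups (matched case-insensitively)
_GROUP_ALIASES = {
    "counterpart": COUNTERPART,
    "comparator": COUNTERPART,
    "comp": COUNTERPART,
    "control": COUNTERPART,
    "conventional": COUNTERPART,
    "gmo": GMO,
    "gm": GMO,
    "test": GMO,
    "reference": REFERENCE,
    "ref": REFERENCE,
}

_CANONICAL_COLUMNS = ("site", "block", "genotype", "group", "analyte", "value")
_OPTIONAL_COLUMNS = ("below_lor", "lor")


class TrialDataError(ValueError):
    """Raised when the content of a trial table is inconsistent."""


class TrialFormatError(ValueError):
    """Raised when a trial table cannot be mapped onto the expected columns."""


@dataclass(frozen=True)
class PlotRecord:
    """A single plot-level measurement of one analyte."""

    site_id: str
    block_id: str
    genotype_id: str
    group: str
    analyte: str
    value: float | None
    below_lor: bool = False
    lor: float | None = None


@dataclass(frozen=True)
class DesignSummary:
    """Size and balance of the experimental design for one analyte."""

    n_sites: int
    n_blocks_per_site: int  # maximum when unequal; see `balanced`
    n_ref_genotypes: int
    balanced: bool
    plots_per_site: dict[str, int] = field(default_factory=dict)

    @property
    def n_s(self) -> int:
        return self.n_sites

    @property
    def n_r(self) -> int:
        return self.n_blocks_per_site

    @property
    def n_g(self) -> int:
        return self.n_ref_genotypes


@dataclass(frozen=True)
class PrepConfig:
    """Preprocessing rules.

    min_quantified
        An analyte is kept only if at least this many results are quantified
        (i.e. not below the reporting limit).  With the default of 2, an
        analyte in which all, or all but one, results are non-detects is
        excluded, since such data carry no usable variation.
    nondetect_rule
        ``half_lor`` replaces each remaining non-detect by half its
        reporting limit; ``exclude`` drops the record instead.
    outlier_list
        Explicit exclusions as ``(analyte, site, block, genotype)`` tuples.
        Outliers are expected to be identified by visual inspection of
        diagnostic plots; no automatic rule is applied.
    transform
        ``ln`` (default) or ``none``.
    """

    min_quantified: int = 2
    nondetect_rule: str = "half_lor"
    outlier_list: tuple[tuple[str, str, str, str], ...] = ()
    transform: str = "ln"

    def __post_init__(self) -> None:
        if self.min_quantified < 2:
            raise ValueError("min_quantified must be >= 2")
        if self.nondetect_rule not in ("half_lor", "exclude"):
            raise ValueError(f"unknown nondetect_rule {self.nondetect_rule!r}")
        if self.transform not in ("ln", "none"):
            raise ValueError(f"unknown transform {self.transform!r}")


@dataclass
class AnalyteDataset:
    """Preprocessed plot-level data for a single analyte.

    ``data`` holds one row per retained plot with columns ``site``,
    ``block``, ``genotype``, ``group`` and ``y`` (the response, on the ln
    scale when ``transform == 'ln'``).  ``exclusions`` logs every input row
    that was removed, with a reason.
    """

    analyte: str
    data: pd.DataFrame
    exclusions: pd.DataFrame
    design: DesignSummary
    transform: str = "ln"

    def __post_init__(self) -> None:
        if not np.isfinite(self.data["y"].to_numpy(float)).all():
            raise TrialDataError(f"{self.analyte}: non-finite response values")

    @property
    def degenerate_design(self) -> bool:
        """True when fewer than two reference genotypes remain.

        Equivalence limits cannot be estimated from a single reference
        variety; downstream code refuses limit estimation in that case.
        """
        return self.design.n_ref_genotypes < 2

    def records(self) -> list[PlotRecord]:
        return [
            PlotRecord(
                site_id=str(r.site),
                block_id=str(r.block),
                genotype_id=str(r.genotype),
                group=str(r.group),
                analyte=self.analyte,
                value=float(r.y),
            )
            for r in self.data.itertuples()
        ]


def _normalize_group(raw: object) -> str:
    key = str(raw).strip().lower()
    if key not in _GROUP_ALIASES:
        raise TrialDataError(f"unrecognized genotype group label {raw!r}")
    return _GROUP_ALIASES[key]


def read_trial_table(
    path: str | Path,
    colmap: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a delimited long-format trial table into a validated frame.

    Parameters
    ----------
    path
        CSV/TSV file with a header row.
    colmap
        Mapping from canonical names (``site``, ``block``, ``genotype``,
        ``group``, ``analyte``, ``value`` and optionally ``below_lor``,
        ``lor``) to the column names used in the file.  Identity by default.
    sep
        Field separator; inferred from the file when omitted.

    Returns a frame with the canonical columns, normalized group labels and
    one row per plot x analyte.  Duplicate (site, block, genotype, analyte)
    rows and non-positive quantified values are rejected.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    colmap = dict(colmap or {})
    rename = {}
    for canon in _CANONICAL_COLUMNS + _OPTIONAL_COLUMNS:
        src = colmap.get(canon, canon)
        if src in raw.columns:
            rename[src] = canon
        elif canon in _CANONICAL_COLUMNS:
            raise TrialFormatError(f"missing mandatory column {src!r} in {path.name}")
    df = raw.rename(columns=rename)[list(rename.values())].copy()
    if "below_lor" not in df.columns:
        df["below_lor"] = False
    df["below_lor"] = df["below_lor"].fillna(False).astype(bool)
    if "lor" not in df.columns:
        df["lor"] = np.nan
    for col in ("site", "block", "genotype", "analyte"):
        df[col] = df[col].astype(str)
    df["group"] = df["group"].map(_normalize_group)

    dup = df.duplicated(subset=["site", "block", "genotype", "analyte"], keep=False)
    if dup.any():
        first = df[dup].iloc[0]
        raise TrialDataError(
            "duplicated plot row: site=%s block=%s genotype=%s analyte=%s"
            % (first["site"], first["block"], first["genotype"], first["analyte"])
        )
    quantified = ~df["below_lor"]
    bad = quantified & ~(df["value"] > 0)
    if bad.any():
        i = df.index[bad][0]
        raise TrialDataError(
            f"non-positive quantified value at input row {i}: "
            f"analyte={df.at[i, 'analyte']!r} value={df.at[i, 'value']!r}"
        )
    _check_group_uniqueness(df)
    return df.reset_index(drop=True)


def _check_group_uniqueness(df: pd.DataFrame) -> None:
    for grp in (GMO, COUNTERPART):
        genos = df.loc[df["group"] == grp, "genotype"].unique()
        if len(genos) > 1:
            raise TrialDataError(
                f"more than one genotype labelled {grp!r}: {sorted(genos)}"
            )


@dataclass(frozen=True)
class ScreenDecision:
    analyte: str
    retained: bool
    n_quantified: int
    n_total: int
    reason: str = ""


def screen_reporting_limit(records: pd.DataFrame, cfg: PrepConfig) -> ScreenDecision:
    """Decide whether an analyte has enough quantified results to analyse."""
    analytes = records["analyte"].unique()
    if len(analytes) != 1:
        raise TrialDataError("screen_reporting_limit expects a single analyte")
    n_q = int((~records["below_lor"]).sum())
    keep = n_q >= cfg.min_quantified
    reason = "" if keep else (
        f"only {n_q} of {len(records)} results quantified "
        f"(minimum {cfg.min_quantified})"
    )
    return ScreenDecision(str(analytes[0]), keep, n_q, len(records), reason)


def substitute_nondetects(
    records: pd.DataFrame, cfg: PrepConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replace below-limit results by half the reporting limit.

    Returns the updated frame and a log of substitutions (one row per
    replaced record) so that downstream outlier review can target them.
    Under the ``exclude`` rule the records are dropped instead and logged.
    """
    df = records.copy()
    mask = df["below_lor"].to_numpy(bool)
    log_rows = df.loc[mask, ["analyte", "site", "block", "genotype", "lor"]].copy()
    if mask.any():
        if df.loc[mask, "lor"].isna().any():
            raise TrialDataError("below-LOR record without a reporting limit value")
        if cfg.nondetect_rule == "half_lor":
            df.loc[mask, "value"] = df.loc[mask, "lor"] / 2.0
            df.loc[mask, "below_lor"] = False
            log_rows["action"] = "substituted half LOR"
        else:
            df = df.loc[~mask]
            log_rows["action"] = "excluded non-detect"
    else:
        log_rows["action"] = pd.Series(dtype=str)
    return df.reset_index(drop=True), log_rows.reset_index(drop=True)


def _design_summary(df: pd.DataFrame) -> DesignSummary:
    blocks_per_site = df.groupby("site")["block"].nunique()
    n_sites = int(df["site"].nunique())
    n_ref = int(df.loc[df["group"] == REFERENCE, "genotype"].nunique())
    plots = df.groupby("site").size().to_dict()
    genotypes = df["genotype"].unique()
    # balanced: every genotype appears exactly once in every block of every site
    cell = df.groupby(["site", "block"])["genotype"].agg(list)
    balanced = bool(
        len(cell) > 0
        and blocks_per_site.nunique() == 1
        and all(sorted(v) == sorted(genotypes) for v in cell)
    )
    return DesignSummary(
        n_sites=n_sites,
        n_blocks_per_site=int(blocks_per_site.max()) if n_sites else 0,
        n_ref_genotypes=n_ref,
        balanced=balanced,
        plots_per_site={str(k): int(v) for k, v in plots.items()},
    )


def finalize_dataset(
    records: pd.DataFrame | AnalyteDataset,
    cfg: PrepConfig,
    prior_exclusions: pd.DataFrame | None = None,
) -> AnalyteDataset:
    """Apply outlier exclusions and the ln transform; compute the design.

    Idempotent: finalizing an already-finalized dataset returns an equal
    dataset (exclusions are already gone and the transform is not
    re-applied).
    """
    if isinstance(records, AnalyteDataset):
        df = records.data.rename(columns={"y": "value"}).copy()
        df["below_lor"] = False
        transform_done = records.transform
        prior = records.exclusions
        analyte = records.analyte
    else:
        df = records.copy()
        transform_done = None
        prior = prior_exclusions
        analyte_vals = df["analyte"].unique()
        if len(analyte_vals) != 1:
            raise TrialDataError("finalize_dataset expects a single analyte")
        analyte = str(analyte_vals[0])
        if df["below_lor"].any():
            raise TrialDataError(
                "non-detects present; run substitute_nondetects first"
            )

    excl_frames = [] if prior is None or prior.empty else [prior]
    key = list(zip([analyte] * len(df), df["site"], df["block"], df["genotype"]))
    out_mask = np.array([k in set(cfg.outlier_list) for k in key], bool)
    if out_mask.any():
        dropped = df.loc[out_mask, ["site", "block", "genotype"]].copy()
        dropped.insert(0, "analyte", analyte)
        dropped["action"] = "excluded outlier"
        excl_frames.append(dropped)
        df = df.loc[~out_mask]

    y = df["value"].to_numpy(float)
    if cfg.transform == "ln" and transform_done != "ln":
        y = np.log(y)
        transform = "ln"
    else:
        transform = transform_done or cfg.transform
    data = pd.DataFrame(
        {
            "site": df["site"].to_numpy(),
            "block": df["block"].to_numpy(),
            "genotype": df["genotype"].to_numpy(),
            "group": df["group"].to_numpy(),
            "y": y,
        }
    )
    exclusions = (
        pd.concat(excl_frames, ignore_index=True)
        if excl_frames
        else pd.DataFrame(columns=["analyte", "site", "block", "genotype", "action"])
    )
    return AnalyteDataset(
        analyte=analyte,
        data=data.reset_index(drop=True),
        exclusions=exclusions,
        design=_design_summary(data),
        transform=transform,
    )


def prepare_analytes(
    table: pd.DataFrame, cfg: PrepConfig | None = None
) -> tuple[dict[str, AnalyteDataset], pd.DataFrame]:
    """Run the full preprocessing pipeline on a validated trial table.

    Returns a dict of :class:`AnalyteDataset` keyed by analyte, plus a tidy
    log frame covering screened-out analytes, substituted non-detects and
    outlier exclusions.
    """
    cfg = cfg or PrepConfig()
    table = table.copy()
    if "below_lor" not in table.columns:
        table["below_lor"] = False
    if "lor" not in table.columns:
        table["lor"] = np.nan
    datasets: dict[str, AnalyteDataset] = {}
    logs: list[pd.DataFrame] = []
    for analyte, sub in table.groupby("analyte", sort=True):
        decision = screen_reporting_limit(sub, cfg)
        if not decision.retained:
            logs.append(
                pd.DataFrame(
                    [
                        {
                            "analyte": analyte,
                            "site": "",
                            "block": "",
                            "genotype": "",
                            "action": f"analyte excluded: {decision.reason}",
                        }
                    ]
                )
            )
            continue
        sub2, nd_log = substitute_nondetects(sub, cfg)
        if not nd_log.empty:
            logs.append(nd_log[["analyte", "site", "block", "genotype", "action"]])
        ds = finalize_dataset(sub2, cfg)
        datasets[str(analyte)] = ds
        if not ds.exclusions.empty:
            logs.append(ds.exclusions)
    log = (
        pd.concat(logs, ignore_index=True)
        if logs
        else pd.DataFrame(columns=["analyte", "site", "block", "genotype", "action"])
    )
    return datasets, log
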