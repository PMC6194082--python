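"""Classification of OTUs into substrate-incorporation ecotypes.

From relative abundances in the representative heavy (H) and light (L)
gradient fractions and the in-situ community, OTUs above a 1 % abundance
filter are assigned one of three ecological response types:

* **I** — rapid, dominant incorporation: strongly enriched in H;
* **II** — slow/minor incorporation: present in H at an abundance
  similar to L;
* **III** — no incorporation: lowest relative abundance in H.

The rule thresholds (fold enrichment, presence floor) are explicit
configuration; the underlying qualitative pattern is general while
clade-level groupings are dataset-specific, so calls are aggregated by
taxonomy string after classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .community import OtuTable, subsample_counts

Ecotype = Literal["I", "II", "III", "unclassified"]


@dataclass(frozen=True)
class EcotypeConfig:
    """Thresholds of the three-type classifier.

    abund_filter : minimum relative abundance (strict >) in any of
        H, L or in-situ for an OTU to be classified (default 1 %).
    fold_enrich : H/L fold change declaring heavy enrichment (type I).
    presence_min : minimum H abundance for a type-II call.
    pseudo : pseudo-abundance guarding ratios against division by zero.
    """

    abund_filter: float = 0.01
    fold_enrich: float = 3.0
    presence_min: float = 0.001
    pseudo: float = 1e-6

    def __post_init__(self) -> None:
        if self.fold_enrich <= 1:
            raise ValueError("fold_enrich must exceed 1")
        if not self.abund_filter > self.presence_min > 0:
            raise ValueError("require abund_filter > presence_min > 0")


@dataclass
class EcotypeCall:
    """Per-OTU classification with the rule that fired."""

    otu_id: str
    h_abund: float
    l_abund: float
    is_abund: float
    ecotype: Ecotype
    rationale: str


def filter_abundant(
    h: pd.Series, l: pd.Series, is_: pd.Series, config: EcotypeConfig | None = None
) -> list[str]:
    """OTUs whose relative abundance exceeds the filter (strict >) in at
    least one of the H, L or in-situ libraries."""
    cfg = config or EcotypeConfig()
    if not (h.index.equals(l.index) and h.index.equals(is_.index)):
        raise ValueError("abundance vectors must be aligned on the same OTU ids")
    keep = pd.concat([h, l, is_], axis=1).max(axis=1) > cfg.abund_filter
    return list(h.index[keep])


def classify_otu(
    h: float, l: float, is_: float, config: EcotypeConfig | None = None
) -> Ecotype:
    """Assign one OTU to ecotype I, II, III or unclassified.

    Rules apply in order: I if H is enriched ≥ fold_enrich over both L
    and in-situ; III if H is strictly lowest; II if the OTU is present
    in H at an abundance within a fold_enrich band of L.  Ties between
    H and L/in-situ fall through to unclassified rather than III.
    """
    cfg = config or EcotypeConfig()
    for name, v in (("h", h), ("l", l), ("is_", is_)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    eps = cfg.pseudo
    if h / max(l, is_, eps) >= cfg.fold_enrich:
        return "I"
    if h < l and h < is_:
        return "III"
    ratio = h / max(l, eps)
    if h >= cfg.presence_min and 1.0 / cfg.fold_enrich < ratio < cfg.fold_enrich:
        return "II"
    return "unclassified"


_RATIONALE = {
    "I": "H enriched >= fold_enrich over max(L, in-situ)",
    "II": "present in H at abundance similar to L",
    "III": "strictly lowest relative abundance in H",
    "unclassified": "no rule fired (ties or below presence floor)",
}


def classify_table(
    h: pd.Series,
    l: pd.Series,
    is_: pd.Series,
    config: EcotypeConfig | None = None,
) -> list[EcotypeCall]:
    """Filter then classify a full set of aligned abundance vectors."""
    cfg = config or EcotypeConfig()
    calls = []
    for otu in filter_abundant(h, l, is_, cfg):
        eco = classify_otu(float(h[otu]), float(l[otu]), float(is_[otu]), cfg)
        calls.append(
            EcotypeCall(
                otu_id=otu,
                h_abund=float(h[otu]),
                l_abund=float(l[otu]),
                is_abund=float(is_[otu]),
                ecotype=eco,
                rationale=_RATIONALE[eco],
            )
        )
    return calls


def ecotype_report(
    table: OtuTable,
    config: EcotypeConfig | None = None,
    depth: int | None = None,
    seed: int = 0,
    late_timepoint: bool = False,
) -> tuple[list[EcotypeCall], pd.DataFrame]:
    """Classify every OTU of an H/L/in-situ comparison and summarise by taxon.

    The table must contain exactly one sample for each of the roles H, L
    and in-situ.  When ``depth`` is given the samples are first rarefied
    to that common depth (matching the normalisation order used for the
    community statistics).  ``late_timepoint`` attaches a cross-feeding
    caveat to type-II calls: at long incubation times, taxa labelled via
    metabolites of primary incorporators are indistinguishable from slow
    incorporators.

    Returns (per-OTU calls, per-taxonomy summary with call counts and
    median abundances per role).
    """
    cfg = config or EcotypeConfig()
    if "role" not in table.sample_meta.columns:
        raise ValueError("sample_meta must carry a 'role' column")
    t = subsample_counts(table, depth, seed) if depth else table
    rel = t.relative()
    role_rows = {}
    for role in ("H", "L", "in-situ"):
        samples = t.sample_meta.index[t.sample_meta["role"] == role]
        if len(samples) == 0:
            raise ValueError(f"missing role {role!r} in sample metadata")
        if len(samples) > 1:
            raise ValueError(f"expected exactly one {role!r} sample, got {list(samples)}")
        role_rows[role] = rel.loc[samples[0]]
    calls = classify_table(role_rows["H"], role_rows["L"], role_rows["in-situ"], cfg)
    if late_timepoint:
        n2 = sum(c.ecotype == "II" for c in calls)
        if n2:
            warnings.warn(
                f"{n2} type-II call(s) at a late timepoint: slow incorporation "
                "cannot be separated from cross-feeding on incorporator products",
                stacklevel=2,
            )
            for c in calls:
                if c.ecotype == "II":
                    c.rationale += " [late timepoint: cross-feeding caveat]"
    rows = []
    for c in calls:
        rows.append(
            {
                "taxonomy": table.otu_meta.get(c.otu_id, "unassigned"),
                "otu": c.otu_id,
                "ecotype": c.ecotype,
                "h": c.h_abund,
                "l": c.l_abund,
                "insitu": c.is_abund,
            }
        )
    per_otu = pd.DataFrame(rows)
    if len(per_otu):
        summary = per_otu.groupby("taxonomy").agg(
            n_otus=("otu", "size"),
            n_type_I=("ecotype", lambda s: int((s == "I").sum())),
            n_type_II=("ecotype", lambda s: int((s == "II").sum())),
            n_type_III=("ecotype", lambda s: int((s == "III").sum())),
            median_h=("h", "median"),
            median_l=("l", "median"),
            median_insitu=("insitu", "median"),
        )
    else:
        summary = pd.DataFrame(
            columns=[
                "n_otus", "n_type_I", "n_type_II", "n_type_III",
                "median_h", "median_l", "median_insitu",
            ]
        )
    return calls, summary


def calls_frame(calls: Sequence[EcotypeCall]) -> pd.DataFrame:
    """Per-OTU calls as the TSV layout otu,h,l,insitu,ecotype,rationale."""
    return pd.DataFrame(
        [
            {
                "otu": c.otu_id,
                "h": c.h_abund,
                "l": c.l_abund,
                "insitu": c.is_abund,
                "ecotype": c.ecotype,
                "rationale": c.rationale,
            }
            for c in calls
        ]
    )
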