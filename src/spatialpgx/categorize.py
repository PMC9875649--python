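"""Pharmacogene family assignment and ROS gene-set derivation.

Families are assigned by ordered symbol-prefix rules (first match wins;
unmatched genes are ``other``).  The ROS (reactive-oxygen-species handling)
set is derived by case-insensitive substring matching of keywords against
GO term *names* — mirroring a batch-query keyword workflow — followed by
removal of the CYP and ABC families.  The exclusion is applied after
matching, so a CYP gene with an oxygen-related term is matched but then
removed.

GO annotations are a versioned input file, never a live query: keyword hits
depend on the GO release, so reproducibility requires freezing the table.
Manual curation of the matched term list is represented as an editable term
blocklist applied before matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import FormatError, ValidationError
from .io import GeneList, _open_text

logger = logging.getLogger(__name__)

#: The ROS keyword list.
DEFAULT_ROS_KEYWORDS = ("oxidative", "stress", "oxygen", "reactive")

#: Families removed from the ROS set after keyword matching.
DEFAULT_ROS_EXCLUDED_FAMILIES = ("CYP", "ABC")

#: Default ordered prefix -> family rules for ADME panels.
DEFAULT_PREFIX_RULES: tuple[tuple[str, str], ...] = (
    ("CYP", "CYP"),
    ("ABC", "ABC"),
    ("SLC", "SLC"),
    ("GST", "GST"),
    ("MGST", "GST"),
    ("UGT", "UGT"),
    ("SULT", "SULT"),
    ("NAT", "NAT"),
    ("ADH", "ADH"),
    ("ALDH", "ALDH"),
)


@dataclass
class CategoryAssignment:
    """Family labels and the ROS flag for a pharmacogene panel."""

    families: dict[str, str] = field(default_factory=dict)
    is_ros: dict[str, bool] = field(default_factory=dict)
    keywords: tuple[str, ...] = ()
    matched_terms: dict[str, list[str]] = field(default_factory=dict)

    def ros_genes(self) -> list[str]:
        return sorted(g for g, flag in self.is_ros.items() if flag)

    def matched_term_set(self) -> list[str]:
        """Distinct GO term names that produced >= 1 ROS match."""
        return sorted({t for terms in self.matched_terms.values() for t in terms})

    def to_frame(self) -> pd.DataFrame:
        genes = sorted(set(self.families) | set(self.is_ros))
        return pd.DataFrame(
            {
                "gene": genes,
                "family": [self.families.get(g, "other") for g in genes],
                "is_ros": [bool(self.is_ros.get(g, False)) for g in genes],
                "matched_terms": [
                    ";".join(self.matched_terms.get(g, [])) for g in genes
                ],
            }
        )


def read_go_annotations(path: str | Path) -> pd.DataFrame:
    """Read a gene -> GO term table (TSV: gene, go_id, term_name)."""
    df = pd.read_csv(_open_text(path), sep="\t", dtype=str, keep_default_na=False)
    cols = list(df.columns)
    if len(cols) < 3:
        raise FormatError(f"{path}: need 3 columns (gene, go_id, term_name)")
    df = df.iloc[:, :3]
    df.columns = ["gene", "go_id", "term_name"]
    if (df["term_name"].str.strip() == "").any():
        raise ValidationError(f"{path}: empty GO term names")
    before = len(df)
    df = df.drop_duplicates(subset=["gene", "go_id"], ignore_index=True)
    if len(df) != before:
        logger.warning("%s: dropped %d duplicate (gene, term) pair(s)", path, before - len(df))
    return df


def assign_families(
    panel: GeneList,
    prefix_rules: Sequence[tuple[str, str]] = DEFAULT_PREFIX_RULES,
) -> CategoryAssignment:
    """Assign each panel gene the family of its first matching prefix rule.

    Explicit families carried on the panel (symbol<TAB>family input) take
    precedence over prefix rules.
    """
    if not prefix_rules:
        raise ValidationError("assign_families: empty rule list")
    families = {}
    for sym in panel.symbols:
        if sym in panel.families:
            families[sym] = panel.families[sym]
            continue
        for prefix, fam in prefix_rules:
            if sym.upper().startswith(prefix.upper()):
                families[sym] = fam
                break
        else:
            families[sym] = "other"
    return CategoryAssignment(families=families)


def ros_genes(
    annotations: pd.DataFrame,
    panel: GeneList,
    keywords: Iterable[str] = DEFAULT_ROS_KEYWORDS,
    excluded_families: Iterable[str] = DEFAULT_ROS_EXCLUDED_FAMILIES,
    blocklist: Iterable[str] = (),
    family_assignment: CategoryAssignment | None = None,
) -> CategoryAssignment:
    """Derive the ROS gene set by GO-term-name keyword matching.

    A panel gene is ROS iff at least one of its GO term names contains at
    least one keyword (case-insensitive substring) AND its family is not in
    ``excluded_families``.  ``blocklist`` lists curated-out term names (or
    GO ids) removed before matching.  Panel genes absent from the annotation
    table are never ROS and are counted in a coverage warning.
    """
    keywords = [k.lower() for k in keywords]
    if not keywords:
        raise ValidationError("ros_genes: empty keyword list")
    excluded = {f.upper() for f in excluded_families}
    block = {b.strip().lower() for b in blocklist}

    assignment = family_assignment or assign_families(panel)
    ann = annotations[annotations["gene"].isin(set(panel.symbols))]
    if block:
        ann = ann[
            ~ann["term_name"].str.strip().str.lower().isin(block)
            & ~ann["go_id"].str.strip().str.lower().isin(block)
        ]

    covered = set(ann["gene"])
    uncovered = [g for g in panel.symbols if g not in covered]
    if uncovered:
        logger.warning(
            "ros_genes: %d of %d panel gene(s) have no GO annotation",
            len(uncovered), len(panel),
        )

    matched_terms: dict[str, list[str]] = {}
    names = ann["term_name"].str.lower()
    hit = pd.Series(False, index=ann.index)
    for kw in keywords:
        hit |= names.str.contains(kw, regex=False)
    for gene, sub in ann[hit].groupby("gene"):
        matched_terms[gene] = sorted(set(sub["term_name"]))

    is_ros = {}
    for g in panel.symbols:
        matched = g in matched_terms
        excluded_fam = assignment.families.get(g, "other").upper() in excluded
        is_ros[g] = matched and not excluded_fam
    n_excluded = sum(1 for g in matched_terms if not is_ros[g])
    logger.info(
        "ros_genes: %d keyword-matched, %d removed by family exclusion, %d final",
        len(matched_terms), n_excluded, sum(is_ros.values()),
    )
    return CategoryAssignment(
        families=dict(assignment.families),
        is_ros=is_ros,
        keywords=tuple(keywords),
        matched_terms={g: t for g, t in matched_terms.items() if is_ros[g]},
    )
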