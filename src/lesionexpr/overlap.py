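"""Cross-lesion overlap classification of differentially expressed gene lists.

Given the significant-gene lists of two contrasts (e.g. HELU vs TDLU and
ADH/DCIS vs HN), genes are partitioned into a common set and two exclusive
sets, optionally checking that shared genes change in the same direction.
A transcription of published lesion profiles — per-gene log2 fold change,
95% CI and FDR for the HELU-vs-TDLU and ADH/DCIS-vs-HN comparisons — ships
with the package for worked examples and regression tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

from .annotation import normalize_symbol

__all__ = [
    "OverlapReport",
    "classify_overlap",
    "check_subset",
    "load_published_profiles",
    "published_gene_lists",
]

_PROFILES_RESOURCE = "published_lesion_profiles.tsv"


def _normalize_list(genes: Iterable[str], label: str) -> set[str]:
    seen: list[str] = [normalize_symbol(g) for g in genes]
    unique = set(seen)
    if len(unique) != len(seen):
        warnings.warn(f"duplicate gene symbols in list {label!r}; deduplicated", stacklevel=3)
    return unique


@dataclass(frozen=True)
class OverlapReport:
    """Partition of two gene lists into common and exclusive sets.

    All member tuples are alphabetically sorted; the three sets are
    disjoint and common ∪ exclusive_first reconstitutes the first list.
    """

    list_labels: tuple[str, str]
    common: tuple[str, ...]
    exclusive_first: tuple[str, ...]
    exclusive_second: tuple[str, ...]
    discordant: tuple[str, ...] = ()

    @property
    def n_common(self) -> int:
        return len(self.common)

    @property
    def n_exclusive_first(self) -> int:
        return len(self.exclusive_first)

    @property
    def n_exclusive_second(self) -> int:
        return len(self.exclusive_second)

    def to_frame(self) -> pd.DataFrame:
        rows = (
            [(g, "common") for g in self.common]
            + [(g, f"exclusive_{self.list_labels[0]}") for g in self.exclusive_first]
            + [(g, f"exclusive_{self.list_labels[1]}") for g in self.exclusive_second]
        )
        return pd.DataFrame(rows, columns=["gene", "category"])


def classify_overlap(
    list_a: Iterable[str],
    list_b: Iterable[str],
    labels: tuple[str, str] = ("first", "second"),
    changes_a: Mapping[str, float] | None = None,
    changes_b: Mapping[str, float] | None = None,
) -> OverlapReport:
    """Partition two significant-gene lists into common/exclusive sets.

    When per-gene fold-change estimates are supplied for both lists,
    shared genes whose changes disagree in sign are additionally reported
    as ``discordant`` (they remain in the common set).
    """
    a = _normalize_list(list_a, labels[0])
    b = _normalize_list(list_b, labels[1])
    common = tuple(sorted(a & b))
    discordant: tuple[str, ...] = ()
    if changes_a is not None and changes_b is not None:
        ca = {normalize_symbol(g): v for g, v in changes_a.items()}
        cb = {normalize_symbol(g): v for g, v in changes_b.items()}
        discordant = tuple(
            g for g in common if g in ca and g in cb and (ca[g] > 0) != (cb[g] > 0)
        )
    return OverlapReport(
        list_labels=labels,
        common=common,
        exclusive_first=tuple(sorted(a - b)),
        exclusive_second=tuple(sorted(b - a)),
        discordant=discordant,
    )


def check_subset(list_a: Iterable[str], list_b: Iterable[str]) -> tuple[bool, set[str]]:
    """Is every gene of *list_a* also in *list_b*?  Returns (flag, missing)."""
    a = _normalize_list(list_a, "first")
    b = _normalize_list(list_b, "second")
    missing = a - b
    return (not missing, missing)


def load_published_profiles() -> pd.DataFrame:
    """Load the packaged transcription of the published lesion profiles.

    One row per gene significant in at least one comparison, with the
    published log2 fold change, 95% CI and FDR for HELU vs TDLU
    (``helu_*`` columns) and ADH/DCIS vs HN (``adh_dcis_*``).  "ND" marks
    confidence bounds the source reported as not determined; fold change
    and FDR are NaN for the one gene absent from the HG-U133A array.
    FDR values printed as a bound (e.g. "<0.001") are taken at the bound.
    """
    with resources.files("lesionexpr.data").joinpath(_PROFILES_RESOURCE).open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    for col in df.columns:
        if col in ("gene", "gene_name", "category"):
            continue
        df[col] = (
            df[col]
            .str.lstrip("<")
            .replace({"ND": None, "NA": None, "": None})
            .astype(float)
        )
    return df


def published_gene_lists(cutoff: float = 0.1) -> dict[str, set[str]]:
    """Significant-gene lists of the two published comparisons at *cutoff*."""
    df = load_published_profiles()
    return {
        "HELU_vs_TDLU": set(df.loc[df["helu_fdr"] < cutoff, "gene"]),
        "ADH_DCIS_vs_HN": set(df.loc[df["adh_dcis_fdr"] < cutoff, "gene"]),
    }
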