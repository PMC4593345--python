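"""Probe-set → gene annotation quality scoring.

On Affymetrix GeneChips a transcript is interrogated by a *probe set* of
short oligonucleotide probes.  Individual probes may fail to match the
intended gene, or may cross-hybridize to additional genes.  Following the
GeneAnnot scoring scheme, each (probe set, gene) connection is summarized
by two fractions in [0, 1]:

* **sensitivity** — the fraction of the probe set's probes that match the
  gene: ``|{probes matching gene}| / |{all probes in the set}|``.  Probes
  matching no gene at all still count in the denominator.
* **specificity** — a match score that down-weights promiscuous probes.
  Each probe matching the gene contributes ``1/k``, where ``k`` is the
  number of distinct genes that probe matches; the sum is divided by the
  number of probes in the set matching *any* gene.  A probe unique to the
  gene contributes a full unit, a probe shared with one other gene half a
  unit, and so on.

The *semi-sum weight* ``(sensitivity + specificity) / 2`` multiplies the
probe set's expression values before gene-level averaging (see
:mod:`lesionexpr.aggregate`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "ProbeMatchTable",
    "parse_probe_match_table",
    "compute_sensitivity",
    "compute_specificity",
    "compute_quality_weights",
]

MATCH_TABLE_COLUMNS = ("probe_set_id", "probe_id", "matched_genes")


def normalize_symbol(symbol: str) -> str:
    """Normalize a gene symbol for comparison: trim whitespace, upper-case."""
    return str(symbol).strip().upper()


@dataclass
class ProbeMatchTable:
    """Probe sets, their probes, and the genes each probe matches.

    ``probes`` maps probe_set_id → ordered list of probe ids; ``matches``
    maps probe_set_id → {probe_id → frozenset of normalized gene symbols}.
    Every probe belongs to exactly one probe set; match sets may be empty.
    """

    probes: dict[str, list[str]] = field(default_factory=dict)
    matches: dict[str, dict[str, frozenset[str]]] = field(default_factory=dict)

    @classmethod
    def from_records(
        cls, records: list[tuple[str, str, set[str] | frozenset[str] | list[str]]]
    ) -> "ProbeMatchTable":
        """Build a validated table from (probe_set_id, probe_id, genes) records."""
        probes: dict[str, list[str]] = {}
        matches: dict[str, dict[str, frozenset[str]]] = {}
        owner: dict[str, str] = {}
        for probe_set_id, probe_id, genes in records:
            probe_set_id = str(probe_set_id).strip()
            probe_id = str(probe_id).strip()
            if probe_id in owner and owner[probe_id] != probe_set_id:
                raise ValueError(
                    f"probe {probe_id!r} listed under two probe sets: "
                    f"{owner[probe_id]!r} and {probe_set_id!r}"
                )
            if probe_set_id in matches and probe_id in matches[probe_set_id]:
                raise ValueError(
                    f"duplicate (probe set, probe) row: ({probe_set_id!r}, {probe_id!r})"
                )
            owner[probe_id] = probe_set_id
            probes.setdefault(probe_set_id, []).append(probe_id)
            matches.setdefault(probe_set_id, {})[probe_id] = frozenset(
                normalize_symbol(g) for g in genes if str(g).strip()
            )
        return cls(probes=probes, matches=matches)

    @property
    def probe_set_ids(self) -> list[str]:
        return list(self.probes)

    def n_probes(self, probe_set_id: str) -> int:
        self._require(probe_set_id)
        return len(self.probes[probe_set_id])

    def genes_of(self, probe_set_id: str) -> set[str]:
        """All genes matched by at least one probe of the probe set."""
        self._require(probe_set_id)
        out: set[str] = set()
        for genes in self.matches[probe_set_id].values():
            out |= genes
        return out

    def _require(self, probe_set_id: str) -> None:
        if probe_set_id not in self.probes:
            raise KeyError(f"unknown probe set {probe_set_id!r}")


def parse_probe_match_table(path) -> ProbeMatchTable:
    """Read a tab-separated probe match table.

    Expected columns: ``probe_set_id``, ``probe_id``, ``matched_genes``
    (semicolon-separated gene symbols, possibly empty).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    missing = [c for c in MATCH_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"match table {path!s} is missing columns: {missing}")
    records = [
        (row.probe_set_id, row.probe_id, [g for g in row.matched_genes.split(";") if g.strip()])
        for row in df.itertuples(index=False)
    ]
    if not records:
        raise ValueError(f"match table {path!s} is empty")
    return ProbeMatchTable.from_records(records)


def compute_sensitivity(table: ProbeMatchTable, probe_set: str, gene: str) -> float:
    """Fraction of the probe set's probes that match *gene*."""
    gene = normalize_symbol(gene)
    table._require(probe_set)
    probe_matches = table.matches[probe_set]
    n_matching = sum(1 for genes in probe_matches.values() if gene in genes)
    return n_matching / len(probe_matches)


def compute_specificity(table: ProbeMatchTable, probe_set: str, gene: str) -> float:
    """Cross-hybridization-penalized match score for (probe set, gene).

    Each probe matching *gene* contributes ``1/k`` (k = number of distinct
    genes it matches); the sum is divided by the number of probes in the
    set matching at least one gene.  Returns 0.0 (with a warning) if no
    probe in the set matches any gene.
    """
    gene = normalize_symbol(gene)
    table._require(probe_set)
    probe_matches = table.matches[probe_set]
    n_matching_any = sum(1 for genes in probe_matches.values() if genes)
    if n_matching_any == 0:
        warnings.warn(
            f"probe set {probe_set!r} has no probe matching any gene; specificity set to 0",
            stacklevel=2,
        )
        return 0.0
    score = sum(1.0 / len(genes) for genes in probe_matches.values() if gene in genes)
    return score / n_matching_any


def compute_quality_weights(table: ProbeMatchTable) -> pd.DataFrame:
    """Score every (probe set, gene) pair with at least one matching probe.

    Returns a DataFrame with columns ``probe_set_id``, ``gene``,
    ``sensitivity``, ``specificity`` and ``weight`` (the semi-sum
    ``(sensitivity + specificity) / 2``), sorted by (gene, probe_set_id).
    """
    if not table.probes:
        raise ValueError("empty probe match table")
    rows = []
    for probe_set_id in table.probe_set_ids:
        for gene in sorted(table.genes_of(probe_set_id)):
            sens = compute_sensitivity(table, probe_set_id, gene)
            spec = compute_specificity(table, probe_set_id, gene)
            rows.append(
                {
                    "probe_set_id": probe_set_id,
                    "gene": gene,
                    "sensitivity": sens,
                    "specificity": spec,
                    "weight": (sens + spec) / 2.0,
                }
            )
    out = pd.DataFrame(
        rows, columns=["probe_set_id", "gene", "sensitivity", "specificity", "weight"]
    )
    return out.sort_values(["gene", "probe_set_id"], kind="stable").reset_index(drop=True)
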