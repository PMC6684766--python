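"""Antigen-specificity annotation against a VDJdb-dialect database.

Chains are matched on (chain, normalized V gene, CDR3 amino acids); a
chain key may carry several specificity records.  For αβ pairs where both
chains are annotated, the pair is classified as matched-epitope,
same-species-different-epitope, or different-species, with precedence
match > same-species > different-species (the most charitable reading of
multi-annotated chains; configurable).
"""

from __future__ import annotations

import enum
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import Chain, Lineage, Repertoire, Scope, normalize_gene

VDJDB_DIALECT = {
    "gene": "gene",
    "cdr3": "cdr3",
    "epitope": "antigen.epitope",
    "species": "antigen.species",
    "mhc_class": "mhc.class",
}


class PairStatus(str, enum.Enum):
    BOTH_UNANNOTATED = "both_unannotated"
    ONE_ANNOTATED = "one_annotated"
    MATCHED_EPITOPE = "matched_epitope"
    SAME_SPECIES_DIFF_EPITOPE = "same_species_diff_epitope"
    DIFF_SPECIES = "diff_species"


@dataclass(frozen=True)
class AnnotationRecord:
    chain: Chain
    v_gene: str
    cdr3_aa: str
    epitope: str
    species: str
    mhc_class: str  # "I", "II", or "unknown"


@dataclass
class AnnotationDB:
    """Specificity records indexed by (chain, V gene, CDR3)."""

    index: dict[tuple[Chain, str, str], tuple[AnnotationRecord, ...]]
    n_records: int

    def lookup(self, chain: Chain, v_gene: str, cdr3: str
               ) -> tuple[AnnotationRecord, ...]:
        return self.index.get((chain, normalize_gene(v_gene), cdr3), ())


def _norm_epitope(e: str) -> str:
    return " ".join(str(e).split()).upper()


def load_annotation_db(
    source: str | Path | pd.DataFrame,
    dialect: Mapping[str, str] | None = None,
    aliases: Mapping[str, str] | None = None,
) -> AnnotationDB:
    """Load a VDJdb-dialect TSV (or DataFrame) into an indexed database.

    The chain is inferred from the gene prefix (TRA*/TRB*).  Duplicate
    rows collapse to a single record; an unrecognized MHC class is kept
    with class 'unknown' after a warning.
    """
    dialect = {**VDJDB_DIALECT, **(dialect or {})}
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in dialect.values() if c not in df.columns]
    if missing:
        raise KeyError(f"annotation table missing columns: {missing}")

    seen: set[AnnotationRecord] = set()
    index: dict[tuple, list[AnnotationRecord]] = defaultdict(list)
    for _, row in df.iterrows():
        gene = normalize_gene(row[dialect["gene"]], aliases)
        chain = Chain.ALPHA if gene.startswith("TRA") else Chain.BETA
        mhc = str(row[dialect["mhc_class"]]).strip().upper().replace("MHC", "")
        mhc = {"I": "I", "II": "II", "1": "I", "2": "II"}.get(mhc, None)
        if mhc is None:
            warnings.warn(f"unknown MHC class {row[dialect['mhc_class']]!r}; "
                          "record retained with class=unknown")
            mhc = "unknown"
        rec = AnnotationRecord(
            chain=chain, v_gene=gene,
            cdr3_aa=str(row[dialect["cdr3"]]).strip().upper(),
            epitope=_norm_epitope(row[dialect["epitope"]]),
            species=str(row[dialect["species"]]).strip(),
            mhc_class=mhc)
        if rec in seen:
            continue
        seen.add(rec)
        index[(rec.chain, rec.v_gene, rec.cdr3_aa)].append(rec)
    return AnnotationDB(index={k: tuple(v) for k, v in index.items()},
                        n_records=len(seen))


@dataclass
class CoverageSummary:
    lineage: Lineage
    chain: Chain
    n_clonotypes: int
    n_annotated: int
    fraction_annotated: float
    by_species: dict[str, int] = field(default_factory=dict)


def annotate_single_chains(
    repertoire: Repertoire, db: AnnotationDB
) -> CoverageSummary | list[CoverageSummary]:
    """Coverage of a repertoire by the database: how many unique clonotypes
    carry at least one specificity annotation, with a species breakdown.

    A single-chain repertoire yields one summary; a paired repertoire
    yields one per chain."""
    def summarize(chain: Chain, vs, cdr3s) -> CoverageSummary:
        n_annot = 0
        by_species: dict[str, int] = defaultdict(int)
        for v, s in zip(vs, cdr3s):
            recs = db.lookup(chain, v, s)
            if recs:
                n_annot += 1
                for sp in {r.species for r in recs}:
                    by_species[sp] += 1
        n = len(vs)
        return CoverageSummary(
            lineage=repertoire.lineage, chain=chain, n_clonotypes=n,
            n_annotated=n_annot,
            fraction_annotated=n_annot / n if n else 0.0,
            by_species=dict(by_species))

    t = repertoire.table
    if repertoire.scope == Scope.PAIRED:
        return [summarize(Chain.ALPHA, t["v_a"], t["cdr3_a"]),
                summarize(Chain.BETA, t["v_b"], t["cdr3_b"])]
    chain = Chain.ALPHA if repertoire.scope == Scope.ALPHA else Chain.BETA
    return summarize(chain, t["v"], t["cdr3"])


@dataclass
class PairConcordance:
    pair_key: tuple
    alpha_records: tuple[AnnotationRecord, ...]
    beta_records: tuple[AnnotationRecord, ...]
    status: PairStatus


@dataclass
class ConcordanceReport:
    pairs: list[PairConcordance]
    counts: dict[str, int]
    species_matrix: pd.DataFrame  # α species × β species, both-annotated pairs

    @property
    def n_both_annotated(self) -> int:
        return (self.counts[PairStatus.MATCHED_EPITOPE.value]
                + self.counts[PairStatus.SAME_SPECIES_DIFF_EPITOPE.value]
                + self.counts[PairStatus.DIFF_SPECIES.value])


def _classify(alpha_recs, beta_recs) -> PairStatus:
    if not alpha_recs and not beta_recs:
        return PairStatus.BOTH_UNANNOTATED
    if not alpha_recs or not beta_recs:
        return PairStatus.ONE_ANNOTATED
    a_ep = {r.epitope for r in alpha_recs}
    b_ep = {r.epitope for r in beta_recs}
    if a_ep & b_ep:
        return PairStatus.MATCHED_EPITOPE
    a_sp = {r.species for r in alpha_recs}
    b_sp = {r.species for r in beta_recs}
    if a_sp & b_sp:
        return PairStatus.SAME_SPECIES_DIFF_EPITOPE
    return PairStatus.DIFF_SPECIES


def paired_concordance(
    pairs: pd.DataFrame | Repertoire,
    db: AnnotationDB,
) -> ConcordanceReport:
    """Classify every unique αβ pair by annotation concordance.

    Only pairs with both chains annotated enter the matched/mismatched
    tally; the species matrix counts those pairs by (α species, β species)
    — its diagonal holds same-species pairs."""
    if isinstance(pairs, Repertoire):
        if pairs.scope != Scope.PAIRED:
            raise ValueError("paired-scope repertoire required")
        table = pairs.table
    else:
        table = pairs
    out: list[PairConcordance] = []
    counts = {s.value: 0 for s in PairStatus}
    cell_counts: dict[tuple[str, str], int] = defaultdict(int)
    for key, row in table.iterrows():
        a_recs = db.lookup(Chain.ALPHA, row["v_a"], row["cdr3_a"])
        b_recs = db.lookup(Chain.BETA, row["v_b"], row["cdr3_b"])
        status = _classify(a_recs, b_recs)
        counts[status.value] += 1
        out.append(PairConcordance(pair_key=key, alpha_records=a_recs,
                                   beta_records=b_recs, status=status))
        if status in (PairStatus.MATCHED_EPITOPE,
                      PairStatus.SAME_SPECIES_DIFF_EPITOPE,
                      PairStatus.DIFF_SPECIES):
            for sp_a in sorted({r.species for r in a_recs}):
                for sp_b in sorted({r.species for r in b_recs}):
                    cell_counts[(sp_a, sp_b)] += 1
    species = sorted({k[0] for k in cell_counts} | {k[1] for k in cell_counts})
    matrix = pd.DataFrame(0, index=species, columns=species, dtype=int)
    for (sa, sb), v in cell_counts.items():
        matrix.loc[sa, sb] = v
    return ConcordanceReport(pairs=out, counts=counts, species_matrix=matrix)


@dataclass
class PromiscuousChain:
    chain: Chain
    key: tuple[str, str]  # (V gene, CDR3)
    n_pairs: int
    partner_epitopes: frozenset[str]
    flagged: bool  # >1 distinct partner epitope


def promiscuity_report(
    pairs: pd.DataFrame | Repertoire,
    db: AnnotationDB,
) -> list[PromiscuousChain]:
    """Chains appearing in ≥2 pairs whose partner chains carry annotations;
    flagged when partners recognize more than one distinct epitope."""
    table = pairs.table if isinstance(pairs, Repertoire) else pairs
    partners: dict[tuple, set[str]] = defaultdict(set)
    seen_pairs: dict[tuple, int] = defaultdict(int)
    for _, row in table.iterrows():
        a_key = (Chain.ALPHA, row["v_a"], row["cdr3_a"])
        b_key = (Chain.BETA, row["v_b"], row["cdr3_b"])
        seen_pairs[a_key] += 1
        seen_pairs[b_key] += 1
        for r in db.lookup(Chain.BETA, row["v_b"], row["cdr3_b"]):
            partners[a_key].add(r.epitope)
        for r in db.lookup(Chain.ALPHA, row["v_a"], row["cdr3_a"]):
            partners[b_key].add(r.epitope)
    out = []
    for key, n in sorted(seen_pairs.items(), key=lambda kv: str(kv[0])):
        if n < 2 or not partners.get(key):
            continue
        eps = frozenset(partners[key])
        out.append(PromiscuousChain(
            chain=key[0], key=(key[1], key[2]), n_pairs=n,
            partner_epitopes=eps, flagged=len(eps) > 1))
    return out
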