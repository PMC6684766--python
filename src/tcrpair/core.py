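"""Data model and primitives for paired αβ TCR clonotype tables.

A single T cell carries one α and one β chain; each chain is identified by
its germline V and J segments plus the CDR3 amino-acid loop (stored
inclusive of the proximal cysteine and terminal phenylalanine).  Cells are
read from TSV, filtered (cells without a CD4/CD8 label and dual-receptor
cells are removed), and deduplicated into unique-clonotype repertoires so
that clonal expansion does not bias downstream statistics.

The clonotype key is V gene + CDR3 amino acids (J excluded).  Analyses of
J usage re-deduplicate from cells with J included in the key.
"""

from __future__ import annotations

import enum
import json
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AA_ALPHABET)

POSITIVE_AA = frozenset("RK")
NEGATIVE_AA = frozenset("DE")

_ALLELE_RE = re.compile(r"\*\d+$")

DEFAULT_DIALECT: dict[str, str] = {
    "cell_id": "cell_id",
    "subject": "subject",
    "lineage": "lineage",
    "v_a": "v_a",
    "j_a": "j_a",
    "cdr3_a": "cdr3_a",
    "v_b": "v_b",
    "j_b": "j_b",
    "cdr3_b": "cdr3_b",
    # optional chain-multiplicity columns
    "n_alpha_chains": "n_alpha_chains",
    "n_beta_chains": "n_beta_chains",
}


class Chain(str, enum.Enum):
    ALPHA = "alpha"
    BETA = "beta"


class Lineage(str, enum.Enum):
    CD4 = "CD4"
    CD8 = "CD8"
    UNKNOWN = "unknown"


class Scope(str, enum.Enum):
    ALPHA = "alpha"
    BETA = "beta"
    PAIRED = "paired"


def normalize_gene(name: str, aliases: Mapping[str, str] | None = None) -> str:
    """Normalize an IMGT gene name: strip allele suffix ('*01'), trim
    whitespace, and apply an optional alias table."""
    g = _ALLELE_RE.sub("", str(name).strip())
    if aliases:
        g = aliases.get(g, g)
    return g


def validate_cdr3(cdr3: str) -> None:
    """Raise ValueError unless *cdr3* is a non-empty 20-letter AA string."""
    if not cdr3:
        raise ValueError("empty CDR3 sequence")
    bad = set(cdr3) - _AA_SET
    if bad:
        raise ValueError(f"invalid amino acids {sorted(bad)!r} in CDR3 {cdr3!r}")


def cdr3_charge(cdr3_aa: str) -> int:
    """Net CDR3 charge: (#R + #K) − (#D + #E).  Histidine is not counted."""
    validate_cdr3(cdr3_aa)
    pos = sum(1 for c in cdr3_aa if c in POSITIVE_AA)
    neg = sum(1 for c in cdr3_aa if c in NEGATIVE_AA)
    return pos - neg


def cdr3_length(cdr3_aa: str) -> int:
    """CDR3 length in residues, inclusive of the flanking C and F."""
    validate_cdr3(cdr3_aa)
    return len(cdr3_aa)


@dataclass(frozen=True)
class Clonotype:
    """One chain's identity: chain tag, V gene, J gene, CDR3 amino acids."""

    chain: Chain
    v_gene: str
    j_gene: str
    cdr3_aa: str

    def __post_init__(self) -> None:
        validate_cdr3(self.cdr3_aa)
        if not self.v_gene or not self.j_gene:
            raise ValueError("v_gene and j_gene must be non-empty")
        prefix = "TRA" if self.chain == Chain.ALPHA else "TRB"
        for g in (self.v_gene, self.j_gene):
            if g.startswith("TRA") or g.startswith("TRB"):
                if not g.startswith(prefix):
                    raise ValueError(
                        f"gene {g!r} inconsistent with chain {self.chain.value}"
                    )

    @property
    def key(self) -> tuple[str, str]:
        """Clonotype key: (V gene, CDR3).  J is deliberately excluded."""
        return (self.v_gene, self.cdr3_aa)


@dataclass(frozen=True)
class PairedTCR:
    """One cell: subject, lineage label, and its α and β clonotypes."""

    cell_id: str
    subject: str
    lineage: Lineage
    alpha: Clonotype
    beta: Clonotype
    n_alpha_chains: int = 1
    n_beta_chains: int = 1

    def __post_init__(self) -> None:
        if self.alpha.chain != Chain.ALPHA or self.beta.chain != Chain.BETA:
            raise ValueError("alpha/beta clonotypes have wrong chain tags")

    def key(self, scope: Scope) -> tuple[str, ...]:
        if scope == Scope.ALPHA:
            return self.alpha.key
        if scope == Scope.BETA:
            return self.beta.key
        return self.alpha.key + self.beta.key


@dataclass
class Repertoire:
    """A deduplicated set of clonotypes for one lineage at one scope.

    ``table`` holds one row per unique clonotype key with representative
    J genes, clone size, and the set of subjects the clonotype was seen in.
    """

    scope: Scope
    lineage: Lineage
    table: pd.DataFrame

    @property
    def members(self) -> frozenset[tuple[str, ...]]:
        return frozenset(self.table.index)

    def __len__(self) -> int:
        return len(self.table)

    def subject_members(self, subject: str) -> frozenset[tuple[str, ...]]:
        mask = self.table["subjects"].map(lambda s: subject in s)
        return frozenset(self.table.index[mask])

    @property
    def subjects(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.table["subjects"]:
            out |= s
        return frozenset(out)


@dataclass
class RowError:
    line: int
    message: str


def _row_to_cell(row: pd.Series, dialect: Mapping[str, str],
                 aliases: Mapping[str, str] | None) -> PairedTCR:
    def col(name: str, default=None):
        c = dialect.get(name, name)
        if c in row.index:
            return row[c]
        return default

    lineage_raw = str(col("lineage", "unknown")).strip()
    try:
        lineage = Lineage(lineage_raw)
    except ValueError:
        lineage = Lineage.UNKNOWN
    alpha = Clonotype(Chain.ALPHA, normalize_gene(col("v_a"), aliases),
                      normalize_gene(col("j_a"), aliases),
                      str(col("cdr3_a")).strip().upper())
    beta = Clonotype(Chain.BETA, normalize_gene(col("v_b"), aliases),
                     normalize_gene(col("j_b"), aliases),
                     str(col("cdr3_b")).strip().upper())
    return PairedTCR(
        cell_id=str(col("cell_id", "")),
        subject=str(col("subject", "")),
        lineage=lineage,
        alpha=alpha,
        beta=beta,
        n_alpha_chains=int(col("n_alpha_chains", 1) or 1),
        n_beta_chains=int(col("n_beta_chains", 1) or 1),
    )


def read_clonotype_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    aliases: Mapping[str, str] | None = None,
    strict: bool = False,
) -> tuple[list[PairedTCR], list[RowError]]:
    """Read a paired-clonotype TSV into cells.

    Parameters
    ----------
    path
        TSV file with one row per cell.
    dialect
        Mapping from canonical field names to column names in the file
        (defaults to ``DEFAULT_DIALECT``).
    aliases
        Optional gene-name alias table applied after allele stripping.
    strict
        When True, any malformed row raises; otherwise malformed rows are
        collected into the returned error list and skipped.

    Returns
    -------
    (cells, errors)
        Cells in file order, and row-level validation errors with 1-based
        data line numbers.
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["v_a", "j_a", "cdr3_a", "v_b", "j_b", "cdr3_b"]
    missing = [dialect[f] for f in required if dialect[f] not in df.columns]
    if missing:
        raise KeyError(f"required columns missing from {path}: {missing}")

    cells: list[PairedTCR] = []
    errors: list[RowError] = []
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        try:
            cells.append(_row_to_cell(row, dialect, aliases))
        except (ValueError, TypeError) as exc:
            if strict:
                raise ValueError(f"line {i}: {exc}") from exc
            errors.append(RowError(line=i, message=str(exc)))
    return cells, errors


def filter_cells(
    cells: Sequence[PairedTCR],
) -> tuple[list[PairedTCR], Counter]:
    """Apply the cell-level exclusion rules.

    Cells lacking a CD4/CD8 lineage label ("no_lineage"), cells with more
    than one distinct α or β chain ("dual_receptor"), and cells with a
    missing chain ("unpaired") are removed.  Returns kept cells and a
    Counter of exclusion reasons.
    """
    kept: list[PairedTCR] = []
    report: Counter = Counter()
    for cell in cells:
        if cell.n_alpha_chains < 1 or cell.n_beta_chains < 1:
            report["unpaired"] += 1
        elif cell.lineage == Lineage.UNKNOWN:
            report["no_lineage"] += 1
        elif cell.n_alpha_chains > 1 or cell.n_beta_chains > 1:
            report["dual_receptor"] += 1
        else:
            kept.append(cell)
    return kept, report


def _cell_record(cell: PairedTCR, scope: Scope, include_j: bool):
    if scope == Scope.ALPHA:
        key = cell.alpha.key
        if include_j:
            key = key + (cell.alpha.j_gene,)
        rec = {"v": cell.alpha.v_gene, "j": cell.alpha.j_gene,
               "cdr3": cell.alpha.cdr3_aa}
    elif scope == Scope.BETA:
        key = cell.beta.key
        if include_j:
            key = key + (cell.beta.j_gene,)
        rec = {"v": cell.beta.v_gene, "j": cell.beta.j_gene,
               "cdr3": cell.beta.cdr3_aa}
    else:
        key = cell.alpha.key + cell.beta.key
        if include_j:
            key = key + (cell.alpha.j_gene, cell.beta.j_gene)
        rec = {"v_a": cell.alpha.v_gene, "j_a": cell.alpha.j_gene,
               "cdr3_a": cell.alpha.cdr3_aa,
               "v_b": cell.beta.v_gene, "j_b": cell.beta.j_gene,
               "cdr3_b": cell.beta.cdr3_aa}
    return key, rec


def deduplicate(
    cells: Sequence[PairedTCR],
    scope: Scope | str = Scope.PAIRED,
    include_j: bool = False,
) -> dict[Lineage, Repertoire]:
    """Collapse cells to unique clonotypes, per lineage.

    Each unique clonotype key — (V, CDR3) per chain, optionally including
    J when ``include_j`` — counts once per lineage; clone sizes and the
    subjects carrying the clonotype are retained as metadata.
    """
    scope = Scope(scope)
    buckets: dict[Lineage, dict] = {Lineage.CD4: {}, Lineage.CD8: {}}
    for cell in cells:
        if cell.lineage not in buckets:
            continue
        key, rec = _cell_record(cell, scope, include_j)
        store = buckets[cell.lineage]
        if key in store:
            store[key]["clone_size"] += 1
            store[key]["subjects"].add(cell.subject)
        else:
            store[key] = {**rec, "clone_size": 1, "subjects": {cell.subject}}
    if scope == Scope.PAIRED:
        base_cols = ["v_a", "j_a", "cdr3_a", "v_b", "j_b", "cdr3_b"]
    else:
        base_cols = ["v", "j", "cdr3"]
    out: dict[Lineage, Repertoire] = {}
    for lineage, store in buckets.items():
        df = pd.DataFrame.from_dict(store, orient="index")
        if df.empty:
            df = pd.DataFrame(columns=base_cols + ["clone_size", "subjects"])
        out[lineage] = Repertoire(scope=scope, lineage=lineage, table=df)
    return out


def aa_frequencies(repertoire: Repertoire, chain: Chain | str | None = None) -> pd.Series:
    """Amino-acid usage frequencies pooled over all CDR3 residues.

    For a paired-scope repertoire, ``chain`` selects which CDR3 column to
    pool; single-chain scopes ignore it.  The 20 entries sum to 1.
    """
    if len(repertoire) == 0:
        raise ValueError("empty repertoire")
    if repertoire.scope == Scope.PAIRED:
        if chain is None:
            raise ValueError("chain required for paired-scope repertoire")
        col = "cdr3_a" if Chain(chain) == Chain.ALPHA else "cdr3_b"
    else:
        col = "cdr3"
    counts = Counter()
    for s in repertoire.table[col]:
        counts.update(s)
    total = sum(counts.values())
    freqs = pd.Series({aa: counts.get(aa, 0) / total for aa in AA_ALPHABET})
    return freqs


def write_repertoires(
    repertoires: Mapping[Lineage, Repertoire], path: str | Path
) -> None:
    """Write the canonical clonotype TSV (one row per unique clonotype per
    lineage)."""
    frames = []
    for lineage, rep in repertoires.items():
        df = rep.table.drop(columns=["subjects"]).copy()
        df["subjects"] = rep.table["subjects"].map(lambda s: ",".join(sorted(s)))
        df.insert(0, "lineage", lineage.value)
        frames.append(df.reset_index(drop=True))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def write_exclusion_report(report: Counter, path: str | Path) -> None:
    Path(path).write_text(json.dumps(dict(report), indent=2, sort_keys=True))


def cells_to_frame(cells: Iterable[PairedTCR]) -> pd.DataFrame:
    """Flatten cells into the canonical cell-level DataFrame."""
    rows = [
        {
            "cell_id": c.cell_id, "subject": c.subject,
            "lineage": c.lineage.value,
            "v_a": c.alpha.v_gene, "j_a": c.alpha.j_gene,
            "cdr3_a": c.alpha.cdr3_aa,
            "v_b": c.beta.v_gene, "j_b": c.beta.j_gene,
            "cdr3_b": c.beta.cdr3_aa,
            "n_alpha_chains": c.n_alpha_chains,
            "n_beta_chains": c.n_beta_chains,
        }
        for c in cells
    ]
    return pd.DataFrame(rows)
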