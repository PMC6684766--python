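"""Synthetic paired CD4/CD8 repertoire generator with planted structure.

The generator emulates the statistical structure the analysis stages are
designed to detect: lineage-biased V/J usage (per-gene log-odds effects),
a configurable Vα×Vβ interaction that creates genuine αβ synergy, CDR3
charge and length effects on lineage, clonal expansion, clones planted in
both lineages with shorter CDR3s, dual-receptor cells, and cells missing
a lineage label.  A companion fixture builder emits a VDJdb-dialect
annotation table with planted matched / mismatched αβ specificities.

Lineage is assigned per clone from a logistic model::

    P(CD4 | clone) = σ(μ + a_{Vα} + b_{Vβ} + c_{Vα,Vβ}
                       + γ·(charge_α + charge_β)
                       + δ_α·(len_α − mean_α) + δ_β·(len_β − mean_β))

so that, with all other effects zero, the population CD4:CD8 odds ratio of
a V gene carrying effect ``a`` is exactly ``exp(a)`` — the property the
parameter-recovery tests rely on.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import (
    Chain,
    Clonotype,
    Lineage,
    PairedTCR,
    Scope,
    deduplicate,
    filter_cells,
)

# Interior CDR3 composition loosely shaped like observed human CDR3 usage
# (glycine/serine rich, cysteine rare); normalized at load time.
_DEFAULT_COMPOSITION = {
    "G": 0.120, "S": 0.110, "A": 0.070, "L": 0.070, "T": 0.070,
    "N": 0.060, "Y": 0.060, "R": 0.055, "V": 0.050, "Q": 0.050,
    "D": 0.050, "E": 0.050, "K": 0.040, "P": 0.040, "F": 0.040,
    "I": 0.040, "W": 0.020, "M": 0.020, "H": 0.020, "C": 0.005,
}

_SPECIES_POOL = ("CMV", "EBV", "InfluenzaA", "HIV-1", "HCV", "YFV")


def _zipf_probs(n: int, exponent: float = 0.8) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1) ** exponent
    return w / w.sum()


@dataclass
class AnnotationPlan:
    """How many specificity annotations to plant in the fixture database."""

    n_matched_pairs: int = 5
    n_diff_species_pairs: int = 2
    n_same_species_pairs: int = 2
    n_alpha_only: int = 10
    n_beta_only: int = 10
    n_decoys: int = 20


@dataclass
class SimConfig:
    """Study conditions for one synthetic paired repertoire.

    Defaults are chosen to resemble a desk-scale version of a pooled
    multi-subject single-cell paired TCR dataset: ~20,000 cells, a CD4
    majority, a skewed gene-usage spectrum over a 30×40 Vα×Vβ universe,
    CDR3 lengths centred near 14 residues, mild clonal expansion, and
    small fractions of shared clones, dual-receptor cells and unlabeled
    cells.
    """

    n_cells: int = 20_000
    p_cd4: float = 0.6
    n_subjects: int = 7

    n_v_alpha: int = 30
    n_v_beta: int = 40
    n_j_alpha: int = 20
    n_j_beta: int = 13
    v_alpha_probs: np.ndarray | None = None
    v_beta_probs: np.ndarray | None = None
    j_alpha_probs: np.ndarray | None = None
    j_beta_probs: np.ndarray | None = None

    # lineage logit: per-gene effects (keyed by gene name), pair interaction,
    # charge coefficient, per-chain centred-length coefficients
    v_alpha_effects: dict[str, float] = field(default_factory=dict)
    v_beta_effects: dict[str, float] = field(default_factory=dict)
    interaction_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    charge_effect: float = 0.0
    length_effect_alpha: float = 0.0
    length_effect_beta: float = 0.0
    intercept: float | None = None  # default: logit(p_cd4)

    mean_len_alpha: float = 14.0
    sd_len_alpha: float = 1.8
    mean_len_beta: float = 14.5
    sd_len_beta: float = 1.8
    min_len: int = 8
    max_len: int = 24
    composition: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_COMPOSITION))

    expansion_geom_p: float = 0.7  # clone size ~ Geometric(p), mean 1/p
    # chains are drawn from finite per-chain pools so that the same α (or β)
    # chain recurs across different pairings, as in real repertoires where
    # single-chain sharing between lineages far exceeds paired sharing.
    # int = pool size; None = every clone gets fresh chains; "auto" scales
    # with the expected clone count (α pool smaller: α chains are less
    # diverse than β).
    alpha_chain_pool: int | None | str = "auto"
    beta_chain_pool: int | None | str = "auto"
    f_shared: float = 0.01
    shared_length_offset: float = 2.0
    f_dual: float = 0.02
    f_unlabeled: float = 0.03

    annotation: AnnotationPlan = field(default_factory=AnnotationPlan)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("f_shared", "f_dual", "f_unlabeled", "p_cd4"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.v_alpha_probs is None:
            self.v_alpha_probs = _zipf_probs(self.n_v_alpha)
        if self.v_beta_probs is None:
            self.v_beta_probs = _zipf_probs(self.n_v_beta)
        if self.j_alpha_probs is None:
            self.j_alpha_probs = _zipf_probs(self.n_j_alpha)
        if self.j_beta_probs is None:
            self.j_beta_probs = _zipf_probs(self.n_j_beta)
        for arr, n, name in (
            (self.v_alpha_probs, self.n_v_alpha, "v_alpha_probs"),
            (self.v_beta_probs, self.n_v_beta, "v_beta_probs"),
            (self.j_alpha_probs, self.n_j_alpha, "j_alpha_probs"),
            (self.j_beta_probs, self.n_j_beta, "j_beta_probs"),
        ):
            arr = np.asarray(arr, dtype=float)
            setattr(self, name.replace("probs", "probs"), arr)
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != {n}")
            if abs(arr.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} does not sum to 1")
        comp_total = sum(self.composition.values())
        self.composition = {k: v / comp_total for k, v in self.composition.items()}
        # validate effect keys against the gene universe
        universe_a = set(self.v_alpha_names)
        universe_b = set(self.v_beta_names)
        for g in self.v_alpha_effects:
            if g not in universe_a:
                raise ValueError(f"effect for unknown Vα gene {g!r}")
        for g in self.v_beta_effects:
            if g not in universe_b:
                raise ValueError(f"effect for unknown Vβ gene {g!r}")
        for ga, gb in self.interaction_effects:
            if ga not in universe_a or gb not in universe_b:
                raise ValueError(f"interaction for unknown pair ({ga}, {gb})")

    @property
    def v_alpha_names(self) -> list[str]:
        return [f"TRAV{i + 1}" for i in range(self.n_v_alpha)]

    @property
    def v_beta_names(self) -> list[str]:
        return [f"TRBV{i + 1}" for i in range(self.n_v_beta)]

    @property
    def j_alpha_names(self) -> list[str]:
        return [f"TRAJ{i + 1}" for i in range(self.n_j_alpha)]

    @property
    def j_beta_names(self) -> list[str]:
        return [f"TRBJ{i + 1}" for i in range(self.n_j_beta)]

    @property
    def mu(self) -> float:
        if self.intercept is not None:
            return self.intercept
        return math.log(self.p_cd4 / (1.0 - self.p_cd4))

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "interaction_effects" in d:
            d["interaction_effects"] = {
                tuple(k.split("|")) if isinstance(k, str) else tuple(k): v
                for k, v in d["interaction_effects"].items()
            }
        if "annotation" in d and isinstance(d["annotation"], Mapping):
            d["annotation"] = AnnotationPlan(**d["annotation"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("v_alpha_probs", "v_beta_probs", "j_alpha_probs", "j_beta_probs"):
            d[k] = np.asarray(d[k]).tolist()
        d["interaction_effects"] = {
            "|".join(k): v for k, v in self.interaction_effects.items()}
        return d


def default_effect_config(seed: int = 0, **overrides) -> SimConfig:
    """The package's reference study conditions: a few moderate single-chain
    V biases, a planted Vα×Vβ interaction block, and weak charge/length
    effects — the qualitative structure the analyses are meant to find."""
    cfg = dict(
        v_alpha_effects={"TRAV1": math.log(2), "TRAV2": -math.log(2),
                         "TRAV3": math.log(1.5)},
        v_beta_effects={"TRBV1": math.log(2), "TRBV2": -math.log(1.5)},
        interaction_effects={
            ("TRAV4", "TRBV3"): math.log(4), ("TRAV5", "TRBV4"): -math.log(4),
            ("TRAV6", "TRBV5"): math.log(3), ("TRAV7", "TRBV6"): -math.log(3),
        },
        charge_effect=0.15,
        length_effect_alpha=0.05,
        length_effect_beta=0.05,
        seed=seed,
    )
    cfg.update(overrides)
    return SimConfig(**cfg)


@dataclass
class GroundTruth:
    """Planted parameters, recoverable downstream."""

    v_alpha_log_or: dict[str, float]
    v_beta_log_or: dict[str, float]
    interaction_effects: dict[tuple[str, str], float]
    synergy_planted: bool
    charge_effect: float
    shared_keys: list[tuple[str, str, str, str]]
    annotation_plant: dict = field(default_factory=dict)


def _draw_lengths(rng, n, mean, sd, lo, hi):
    ln = np.rint(rng.normal(mean, sd, size=n)).astype(int)
    return np.clip(ln, lo, hi)


def _draw_cdr3s(rng, lengths: np.ndarray, letters: np.ndarray,
                probs: np.ndarray) -> tuple[list[str], np.ndarray]:
    """Draw CDR3s of the given total lengths (C + interior + F); returns
    the sequences and their net charges."""
    interior = lengths - 2
    total = int(interior.sum())
    flat_idx = rng.choice(len(letters), size=total, p=probs)
    flat = letters[flat_idx]
    charge_map = np.zeros(len(letters), dtype=int)
    for i, aa in enumerate(letters):
        if aa in "RK":
            charge_map[i] = 1
        elif aa in "DE":
            charge_map[i] = -1
    bounds = np.concatenate([[0], np.cumsum(interior)])
    charges = np.add.reduceat(charge_map[flat_idx], bounds[:-1]) \
        if total else np.zeros(len(lengths), dtype=int)
    charges = np.where(interior > 0, charges, 0)
    seqs = []
    for i in range(len(lengths)):
        seqs.append("C" + "".join(flat[bounds[i]:bounds[i + 1]]) + "F")
    return seqs, charges


def generate_repertoire(config: SimConfig) -> tuple[list[PairedTCR], GroundTruth]:
    """Generate exactly ``config.n_cells`` cells (before any filtering).

    Clones are drawn until their expanded clone sizes cover ``n_cells``;
    shared clones are emitted into both lineages with CDR3 lengths drawn
    from a distribution shifted shorter by ``shared_length_offset``.
    Identical seeds yield identical output.
    """
    rng = np.random.default_rng(config.seed)
    mean_size = 1.0 / config.expansion_geom_p
    # oversample clones; truncated to n_cells after expansion
    n_clones = int(config.n_cells / mean_size * 1.4) + 50
    expected_clones = config.n_cells * config.expansion_geom_p

    letters = np.array(list(config.composition))
    comp = np.array([config.composition[a] for a in letters])

    def draw_chain(n, n_v, v_probs, n_j, j_probs, mean_len, sd_len):
        v = rng.choice(n_v, size=n, p=v_probs)
        j = rng.choice(n_j, size=n, p=j_probs)
        ln = _draw_lengths(rng, n, mean_len, sd_len,
                           config.min_len, config.max_len)
        cdr3, q = _draw_cdr3s(rng, ln, letters, comp)
        return v, j, ln, np.array(cdr3, dtype=object), q

    def pool_size(setting, factor):
        if setting == "auto":
            return max(100, int(factor * expected_clones))
        return setting

    shared = rng.random(n_clones) < config.f_shared

    def chain_arrays(pool_setting, factor, n_v, v_probs, n_j, j_probs,
                     mean_len, sd_len):
        k = pool_size(pool_setting, factor)
        if k:
            pv, pj, pl, pc, pq = draw_chain(k, n_v, v_probs, n_j, j_probs,
                                            mean_len, sd_len)
            idx = rng.integers(k, size=n_clones)
            v, j, ln = pv[idx], pj[idx], pl[idx]
            cdr3, q = pc[idx], pq[idx]
        else:
            v, j, ln, cdr3, q = draw_chain(n_clones, n_v, v_probs, n_j,
                                           j_probs, mean_len, sd_len)
        # planted shared clones always carry fresh chains with a shorter
        # length distribution, so their CDR3 properties are controlled
        n_sh = int(shared.sum())
        if n_sh:
            sv, sj, sl, sc, sq = draw_chain(
                n_sh, n_v, v_probs, n_j, j_probs,
                mean_len - config.shared_length_offset, sd_len)
            v = v.copy(); j = j.copy(); ln = ln.copy()
            cdr3 = cdr3.copy(); q = q.copy()
            v[shared], j[shared], ln[shared] = sv, sj, sl
            cdr3[shared], q[shared] = sc, sq
        return v, j, ln, cdr3, q

    va, ja, la, cdr3a, qa = chain_arrays(
        config.alpha_chain_pool, 3.0, config.n_v_alpha, config.v_alpha_probs,
        config.n_j_alpha, config.j_alpha_probs,
        config.mean_len_alpha, config.sd_len_alpha)
    vb, jb, lb, cdr3b, qb = chain_arrays(
        config.beta_chain_pool, 6.0, config.n_v_beta, config.v_beta_probs,
        config.n_j_beta, config.j_beta_probs,
        config.mean_len_beta, config.sd_len_beta)

    a_vec = np.zeros(config.n_v_alpha)
    for g, e in config.v_alpha_effects.items():
        a_vec[config.v_alpha_names.index(g)] = e
    b_vec = np.zeros(config.n_v_beta)
    for g, e in config.v_beta_effects.items():
        b_vec[config.v_beta_names.index(g)] = e
    c_mat = np.zeros((config.n_v_alpha, config.n_v_beta))
    for (ga, gb), e in config.interaction_effects.items():
        c_mat[config.v_alpha_names.index(ga), config.v_beta_names.index(gb)] = e

    logit = (config.mu + a_vec[va] + b_vec[vb] + c_mat[va, vb]
             + config.charge_effect * (qa + qb)
             + config.length_effect_alpha * (la - config.mean_len_alpha)
             + config.length_effect_beta * (lb - config.mean_len_beta))
    p_cd4 = 1.0 / (1.0 + np.exp(-logit))
    is_cd4 = rng.random(n_clones) < p_cd4

    sizes = rng.geometric(config.expansion_geom_p, size=n_clones)
    sizes_shared = rng.geometric(config.expansion_geom_p, size=n_clones)
    subj = rng.integers(config.n_subjects, size=n_clones)

    # expand clones into cells until n_cells is reached
    records: list[tuple[int, bool]] = []  # (clone index, is_cd4 for this copy)
    total = 0
    for i in range(n_clones):
        if total >= config.n_cells:
            break
        if shared[i]:
            for lin in (True, False):
                s = int(sizes[i] if lin else sizes_shared[i])
                s = min(s, config.n_cells - total)
                records.extend((i, lin) for _ in range(s))
                total += s
                if total >= config.n_cells:
                    break
        else:
            s = min(int(sizes[i]), config.n_cells - total)
            records.extend((i, bool(is_cd4[i])) for _ in range(s))
            total += s
    if total < config.n_cells:
        raise RuntimeError("clone oversampling insufficient; raise factor")

    u = rng.random(len(records))
    cells: list[PairedTCR] = []
    names_va, names_vb = config.v_alpha_names, config.v_beta_names
    names_ja, names_jb = config.j_alpha_names, config.j_beta_names
    for k, (i, lin_cd4) in enumerate(records):
        lineage = Lineage.CD4 if lin_cd4 else Lineage.CD8
        n_a = n_b = 1
        if u[k] < config.f_dual:
            n_a = 2
        elif u[k] < config.f_dual + config.f_unlabeled:
            lineage = Lineage.UNKNOWN
        cells.append(PairedTCR(
            cell_id=f"cell{k:07d}",
            subject=f"S{subj[i] + 1}",
            lineage=lineage,
            alpha=Clonotype(Chain.ALPHA, names_va[va[i]], names_ja[ja[i]], cdr3a[i]),
            beta=Clonotype(Chain.BETA, names_vb[vb[i]], names_jb[jb[i]], cdr3b[i]),
            n_alpha_chains=n_a,
            n_beta_chains=n_b,
        ))

    used = sorted({i for i, _ in records})
    shared_keys = [
        (names_va[va[i]], cdr3a[i], names_vb[vb[i]], cdr3b[i])
        for i in used if shared[i]
    ]
    truth = GroundTruth(
        v_alpha_log_or=dict(config.v_alpha_effects),
        v_beta_log_or=dict(config.v_beta_effects),
        interaction_effects=dict(config.interaction_effects),
        synergy_planted=any(e != 0 for e in config.interaction_effects.values()),
        charge_effect=config.charge_effect,
        shared_keys=shared_keys,
    )
    return cells, truth


def _random_epitope(rng) -> str:
    letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    return "".join(rng.choice(letters, size=9))


def generate_annotation_db(
    cells: Sequence[PairedTCR],
    config: SimConfig,
    truth: GroundTruth | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Build a VDJdb-dialect annotation TSV with planted pair structure.

    Plants, among the unique αβ clonotypes of the filtered repertoire:
    matched pairs (α and β annotated with the same epitope), pairs whose
    chains recognize epitopes from different species, pairs recognizing
    different epitopes of the same species, and singleton α/β annotations.
    The plan lives in ``config.annotation``; the planted assignments are
    recorded on ``truth.annotation_plant`` when a truth object is given.

    Columns follow the VDJdb dialect: gene, cdr3, antigen.epitope,
    antigen.species, mhc.class.
    """
    plan = config.annotation
    rng = np.random.default_rng(config.seed + 7 if seed is None else seed)

    kept, _ = filter_cells(cells)
    reps = deduplicate(kept, Scope.PAIRED)
    table = pd.concat([reps[Lineage.CD4].table, reps[Lineage.CD8].table])
    # drop clonotypes present in both lineages, then require globally unique
    # chain keys so every planted annotation hits exactly one pair
    table = table[~table.index.duplicated(keep=False)]
    akey = list(zip(table["v_a"], table["cdr3_a"]))
    bkey = list(zip(table["v_b"], table["cdr3_b"]))
    a_counts = pd.Series(akey).value_counts()
    b_counts = pd.Series(bkey).value_counts()
    unique_mask = np.array([
        a_counts[ak] == 1 and b_counts[bk] == 1 for ak, bk in zip(akey, bkey)
    ])
    pool = table[unique_mask]

    n_pairs = (plan.n_matched_pairs + plan.n_diff_species_pairs
               + plan.n_same_species_pairs)
    n_single = plan.n_alpha_only + plan.n_beta_only
    if n_pairs + n_single > len(pool):
        raise ValueError(
            f"annotation plan needs {n_pairs + n_single} distinct clonotypes, "
            f"only {len(pool)} available")
    pick = rng.choice(len(pool), size=n_pairs + n_single, replace=False)
    chosen = pool.iloc[pick]

    rows: list[dict] = []
    plant = {"matched": [], "diff_species": [], "same_species": [],
             "alpha_only": [], "beta_only": []}

    def add(gene, cdr3, epitope, species, mhc):
        rows.append({"gene": gene, "cdr3": cdr3, "antigen.epitope": epitope,
                     "antigen.species": species, "mhc.class": mhc})

    idx = 0
    for _ in range(plan.n_matched_pairs):
        r = chosen.iloc[idx]; idx += 1
        sp = _SPECIES_POOL[rng.integers(3)]  # common viruses
        ep = _random_epitope(rng)
        add(r["v_a"], r["cdr3_a"], ep, sp, "I")
        add(r["v_b"], r["cdr3_b"], ep, sp, "I")
        plant["matched"].append(chosen.index[idx - 1])
    for _ in range(plan.n_diff_species_pairs):
        r = chosen.iloc[idx]; idx += 1
        sp_a, sp_b = rng.choice(len(_SPECIES_POOL), size=2, replace=False)
        add(r["v_a"], r["cdr3_a"], _random_epitope(rng), _SPECIES_POOL[sp_a], "I")
        add(r["v_b"], r["cdr3_b"], _random_epitope(rng), _SPECIES_POOL[sp_b], "I")
        plant["diff_species"].append(chosen.index[idx - 1])
    for _ in range(plan.n_same_species_pairs):
        r = chosen.iloc[idx]; idx += 1
        sp = _SPECIES_POOL[rng.integers(len(_SPECIES_POOL))]
        ep_a = _random_epitope(rng)
        ep_b = _random_epitope(rng)
        while ep_b == ep_a:
            ep_b = _random_epitope(rng)
        add(r["v_a"], r["cdr3_a"], ep_a, sp, "I")
        add(r["v_b"], r["cdr3_b"], ep_b, sp, "I")
        plant["same_species"].append(chosen.index[idx - 1])
    for _ in range(plan.n_alpha_only):
        r = chosen.iloc[idx]; idx += 1
        add(r["v_a"], r["cdr3_a"], _random_epitope(rng),
            _SPECIES_POOL[rng.integers(len(_SPECIES_POOL))], "I")
        plant["alpha_only"].append(chosen.index[idx - 1])
    for _ in range(plan.n_beta_only):
        r = chosen.iloc[idx]; idx += 1
        add(r["v_b"], r["cdr3_b"], _random_epitope(rng),
            _SPECIES_POOL[rng.integers(len(_SPECIES_POOL))], "I")
        plant["beta_only"].append(chosen.index[idx - 1])
    # decoy rows matching nothing in the repertoire
    for _ in range(plan.n_decoys):
        chain = rng.integers(2)
        gene = f"TRAV{rng.integers(config.n_v_alpha) + 1}" if chain == 0 \
            else f"TRBV{rng.integers(config.n_v_beta) + 1}"
        add(gene, "C" + _random_epitope(rng) + "F",
            _random_epitope(rng),
            _SPECIES_POOL[rng.integers(len(_SPECIES_POOL))], "I")

    if truth is not None:
        truth.annotation_plant = plant
    return pd.DataFrame(rows)
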