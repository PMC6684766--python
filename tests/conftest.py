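import pytest

from tcrpair.core import (
    Chain,
    Clonotype,
    Lineage,
    PairedTCR,
    Scope,
    deduplicate,
    filter_cells,
)
from tcrpair.simulate import default_effect_config, generate_repertoire


def make_cell(cell_id="c1", subject="S1", lineage=Lineage.CD4,
              v_a="TRAV1", j_a="TRAJ1", cdr3_a="CAVMDSSYKLIF",
              v_b="TRBV1", j_b="TRBJ1", cdr3_b="CASSLGETQYF",
              n_alpha=1, n_beta=1) -> PairedTCR:
    return PairedTCR(
        cell_id=cell_id, subject=subject, lineage=lineage,
        alpha=Clonotype(Chain.ALPHA, v_a, j_a, cdr3_a),
        beta=Clonotype(Chain.BETA, v_b, j_b, cdr3_b),
        n_alpha_chains=n_alpha, n_beta_chains=n_beta)


@pytest.fixture(scope="session")
def reference_run():
    """One filtered synthetic repertoire shared across tests: the default
    study conditions at a reduced cell count."""
    cfg = default_effect_config(seed=11, n_cells=6000)
    cells, truth = generate_repertoire(cfg)
    kept, report = filter_cells(cells)
    reps = {scope: deduplicate(kept, scope) for scope in Scope}
    return {"config": cfg, "cells": cells, "truth": truth, "kept": kept,
            "report": report, "reps": reps}
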