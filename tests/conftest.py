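import numpy as np
import pytest
from hypothesis import settings

import toxscreen as ts

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

#: seed of the default archetype-recovery study shared across the suite
RECOVERY_SEED = 7


@pytest.fixture(scope="session")
def recovery_dataset():
    """Default recovery study: 20 chemicals per planted archetype + 400 nulls."""
    return ts.default_recovery_dataset(RECOVERY_SEED)


@pytest.fixture(scope="session")
def recovery_iv(recovery_dataset):
    return ts.build_input_matrix(recovery_dataset.matrix)


@pytest.fixture(scope="session")
def recovery_results(recovery_iv):
    """Ranked results for every bundled model on the recovery dataset."""
    return {
        model.model_name: ts.toxpi_scores(recovery_iv, model)
        for model in ts.bundled_models()
    }


@pytest.fixture
def tiny_matrix():
    """2 chemicals x 3 assays with one active hit each and one untested pair."""
    chems = [ts.ChemicalRecord("C1", "one"), ts.ChemicalRecord("C2", "two")]
    assays = [ts.AssayEndpoint(a) for a in ("A1", "A2", "A3")]
    results = [
        ts.PairResult("C1", "A1", ts.HitCall.ACTIVE, 1.0, 5.4),
        ts.PairResult("C1", "A2", ts.HitCall.INACTIVE),
        ts.PairResult("C2", "A1", ts.HitCall.INACTIVE),
        ts.PairResult("C2", "A2", ts.HitCall.ACTIVE, 0.1, 3.0),
        ts.PairResult("C2", "A3", ts.HitCall.SINGLE_CONC),
        # (C1, A3) untested: encoded by absence
    ]
    return ts.HTSMatrix(chems, assays, results)


def random_hts_matrix(seed, n_chem=6, n_assay=8, p_active=0.4, p_untested=0.2):
    """Small random matrix for oracle comparisons and round-trip tests."""
    rng = np.random.default_rng(seed)
    chems = [ts.ChemicalRecord(f"C{i}", f"chem {i}") for i in range(n_chem)]
    assays = [ts.AssayEndpoint(f"A{j}") for j in range(n_assay)]
    results = []
    for c in chems:
        for a in assays:
            u = rng.random()
            if u < p_untested:
                continue
            if u < p_untested + p_active:
                ac50 = float(10.0 ** rng.normal(0.0, 1.0))
                z = float(rng.uniform(-1.0, 12.0))
                results.append(
                    ts.PairResult(c.chemical_id, a.assay_id, ts.HitCall.ACTIVE, ac50, z)
                )
            else:
                results.append(ts.PairResult(c.chemical_id, a.assay_id, ts.HitCall.INACTIVE))
    return ts.HTSMatrix(chems, assays, results)
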