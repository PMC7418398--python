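import numpy as np
import pandas as pd
import pytest

from pqtlkit.datatypes import PeptideSignalTable, ProteinMatrix
from pqtlkit.simulate import PlantedEffect, SimulationConfig


def make_peptide_table(rows, samples=("S1",)):
    """rows: (peptide_id, protein_ids tuple, {sample: area})."""
    recs = []
    for pid, prots, areas in rows:
        rec = {"peptide_id": pid, "sequence": f"SEQ{pid}", "protein_ids": tuple(prots)}
        for s in samples:
            rec[s] = areas.get(s, np.nan)
        recs.append(rec)
    cols = ["peptide_id", "sequence", "protein_ids", *samples]
    df = pd.DataFrame(recs, columns=cols)
    return PeptideSignalTable(table=df, samples=list(samples))


def make_meta(masses, chrom="1", start=1000, length=2000):
    return pd.DataFrame([
        {"protein": p, "gene": f"G_{p}", "chrom": chrom,
         "start": start, "end": start + length, "mass": m}
        for p, m in masses.items()])


def make_protein_matrix(values: dict, samples, masses=None):
    df = pd.DataFrame(values, index=samples).T
    df.columns = samples
    meta = make_meta(masses or {p: 50_000.0 for p in values})
    return ProteinMatrix(values=df, meta=meta)


@pytest.fixture
def small_config():
    return SimulationConfig(n_samples=80, n_variants=120, n_proteins=12, seed=11,
                            planted_effects=[PlantedEffect(5, 0, 1.5, "local")])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
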