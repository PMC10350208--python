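import pandas as pd
import pytest

from ascrep import SimConfig, assign_lineages, generate, validate_repertoire


def make_repertoire(rows, subject="S1", population="pop2"):
    """Build a Repertoire frame from (sequence_id, v_call, j_call, junction[, dup, mut]) rows."""
    from ascrep.airr_io import Repertoire

    recs = []
    for row in rows:
        sid, v, j, junction = row[:4]
        dup = row[4] if len(row) > 4 else 1
        mut = row[5] if len(row) > 5 else float("nan")
        recs.append(
            {
                "sequence_id": sid,
                "v_call": v,
                "j_call": j,
                "junction": junction,
                "junction_length": len(junction),
                "duplicate_count": dup,
                "v_mutation_count": mut,
                "population": population,
                "subject": subject,
            }
        )
    return Repertoire(subject, population, pd.DataFrame(recs))


@pytest.fixture(scope="session")
def small_sim():
    """A small 4-population simulated subject with moderate sharing."""
    return generate(SimConfig(n_lineages=120, sequences_per_population=900,
                              sharing=0.4, shm_lambda=8.0, seed=11))


@pytest.fixture(scope="session")
def small_table(small_sim):
    reps = [validate_repertoire(r)[0] for r in small_sim.repertoires]
    return assign_lineages(reps)
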