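import numpy as np
import pandas as pd
import pytest

from faersig import (SyntheticConfig, build_drug_event_cells, build_pt_tables,
                     deduplicate, generate_dataset, select_primary_suspect)


@pytest.fixture(scope="session")
def bundle():
    """Moderate synthetic corpus shared by ingestion/linkage tests."""
    return generate_dataset(SyntheticConfig(n_reports=4000, seed=123))


@pytest.fixture(scope="session")
def screened(bundle):
    """Deduplicated cohort, index ids and contingency cells for `bundle`."""
    demo = bundle.tables["DEMO"]
    drug = bundle.tables["DRUG"]
    reac = bundle.tables["REAC"]
    dd = deduplicate(demo)
    survivors = set(dd["primaryid"].astype(str))
    ids = select_primary_suspect(drug, ["osilodrostat"]) & survivors
    events = reac.loc[reac["primaryid"].astype(str).isin(survivors),
                      ["primaryid", "pt"]]
    cells = build_pt_tables(events, ids)
    ps = drug[drug["role_cod"] == "PS"].drop_duplicates("primaryid")
    all_cells = build_drug_event_cells(
        events, ps.set_index(ps["primaryid"].astype(str))["drugname"])
    return {"demo_dedup": dd, "index_ids": ids, "events": events,
            "cells": cells, "all_cells": all_cells}


def make_demo(rows):
    """DEMO-like frame from (caseid, fda_dt, primaryid) triples."""
    return pd.DataFrame(
        [{"primaryid": str(p), "caseid": str(c), "fda_dt": str(f)}
         for c, f, p in rows],
        columns=["primaryid", "caseid", "fda_dt"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
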