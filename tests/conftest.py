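import numpy as np
import pandas as pd
import pytest

from jellydiet.io import FeatureTable, SampleMetadata, TaxonomyTable, RANKS
from jellydiet.synthio import PredatorSpec, SimConfig, SimTaxon


def make_taxon(tid, det=(1.0, 1.0), gel=False, **ranks):
    return SimTaxon(tid, {r: ranks.get(r, "") for r in RANKS},
                    is_gelatinous=gel, detectability=det)


def small_pool(n=5, det=None):
    """n prey taxa with distinct families; optional per-taxon detectability."""
    pool = []
    for i in range(n):
        pool.append(make_taxon(
            f"prey_{i}", det=(det[i] if det else (1.0, 1.0)),
            kingdom="Animalia", phylum="Arthropoda", order="Euphausiacea",
            family=f"Family{i}", genus=f"Genus{i}", species=f"Genus{i} sp{i}",
            **{"class": "Malacostraca"},
        ))
    return pool


def small_config(seed=0, n_taxa=5, n_stomachs=3, n_contaminants=1, **overrides):
    """A compact two-predator configuration for fast property tests."""
    pool = overrides.pop("taxon_pool", small_pool(n_taxa))
    predators = overrides.pop("predators", [
        PredatorSpec("Gadus morhua", "Gadiformes", {"west": n_stomachs, "east": n_stomachs}),
        PredatorSpec("Argentina silus", "Argentiniformes", {"west": n_stomachs}),
    ])
    conc = overrides.pop("diet_concentration", None)
    if conc is None:
        rng = np.random.default_rng(seed + 7)
        conc = {p.species: 0.4 + rng.random(len(pool)) for p in predators}
    defaults = dict(
        seed=seed, predators=predators, taxon_pool=pool, diet_concentration=conc,
        n_extraction_blanks=2, n_pcr_negatives=1,
        depth_log_mean=np.log(20000.0), depth_log_sd=0.3,
        predator_read_fraction=(1.0, 4.0), n_contaminants=n_contaminants,
        contaminant_blank_load=120.0, contaminant_sample_load=1.5,
        tag_switch_rate=0.002,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


def make_metadata(stomachs, blanks=(), negatives=()):
    """stomachs: list of (sample_id, species, order, region)."""
    rows = []
    for sid, species, order, region in stomachs:
        rows.append({"sample_id": sid, "sample_type": "stomach",
                     "predator_species": species, "predator_order": order,
                     "region": region, "station": f"{region}_01"})
    for sid in blanks:
        rows.append({"sample_id": sid, "sample_type": "extraction_blank",
                     "predator_species": "", "predator_order": "", "region": "",
                     "station": ""})
    for sid in negatives:
        rows.append({"sample_id": sid, "sample_type": "pcr_negative",
                     "predator_species": "", "predator_order": "", "region": "",
                     "station": ""})
    return SampleMetadata(pd.DataFrame(rows).set_index("sample_id"))


def make_taxonomy(marker, rows):
    """rows: dict feature_id -> dict with lineage ranks / scores / flags."""
    recs = []
    for fid, spec in rows.items():
        rec = {"feature_id": fid}
        for r in RANKS:
            rec[r] = spec.get(r, "")
        rec["best_identity"] = spec.get("best_identity", np.nan)
        rec["phylum_bootstrap"] = spec.get("phylum_bootstrap", np.nan)
        for flag in ("is_gelatinous", "is_benthic_gelatinous", "is_terrestrial",
                     "excluded_group"):
            rec[flag] = spec.get(flag, False)
        rec["regionally_plausible"] = spec.get("regionally_plausible", True)
        recs.append(rec)
    columns = (["feature_id"] + list(RANKS) + ["best_identity", "phylum_bootstrap",
               "is_gelatinous", "is_benthic_gelatinous", "is_terrestrial",
               "excluded_group", "regionally_plausible"])
    df = pd.DataFrame(recs, columns=columns)
    if not recs:
        df["regionally_plausible"] = df["regionally_plausible"].astype(bool)
    return TaxonomyTable(marker, df.set_index("feature_id"))


def feature_table(marker, data: dict, samples: list):
    """data: feature_id -> list of counts aligned with samples."""
    return FeatureTable(
        marker,
        pd.DataFrame.from_dict(data, orient="index", columns=samples),
    )


@pytest.fixture
def cascade_fixture():
    """A 6-feature, 4-stomach + 2-blank table whose full-cascade outcome was
    computed independently by hand (see test_curation / test_acceptance)."""
    samples = ["S1", "S2", "S3", "S4", "B1", "B2"]
    table = feature_table("COI", {
        "cont_a": [30, 30, 19, 10, 6, 5],     # blank share 11/100 > 0.10
        "cont_b": [40, 30, 10, 10, 6, 4],     # blank share 10/100, retained
        "lowid": [50, 0, 0, 0, 0, 0],         # best identity 0.84
        "prey1": [600, 4, 500, 400, 0, 0],    # 4-read cell in S2
        "pred_gm": [300, 200, 100, 0, 0, 0],  # predator species feature
        "prey2": [400, 970, 400, 589, 0, 0],
    }, samples)
    tax = make_taxonomy("COI", {
        "cont_a": {"kingdom": "Animalia", "family": "ContamA", "best_identity": 0.95},
        "cont_b": {"kingdom": "Animalia", "family": "ContamB", "best_identity": 0.95},
        "lowid": {"kingdom": "Animalia", "family": "LowIdFam", "best_identity": 0.84},
        "prey1": {"kingdom": "Animalia", "family": "PreyFam1",
                  "species": "Prey one", "best_identity": 0.99},
        "pred_gm": {"kingdom": "Animalia", "order": "Gadiformes",
                    "family": "Gadidae", "genus": "Gadus",
                    "species": "Gadus morhua", "best_identity": 0.98},
        "prey2": {"kingdom": "Animalia", "family": "PreyFam2",
                  "species": "Prey two", "best_identity": 0.95},
    })
    meta = make_metadata(
        stomachs=[("S1", "Gadus morhua", "Gadiformes", "west"),
                  ("S2", "Gadus morhua", "Gadiformes", "west"),
                  ("S3", "Argentina silus", "Argentiniformes", "east"),
                  ("S4", "Argentina silus", "Argentiniformes", "east")],
        blanks=["B1", "B2"],
    )
    return table, tax, meta
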