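from __future__ import annotations

import pytest

from oralpv.icsr import ICSRCollection, ICSRRecord
from oralpv.simulate import SimConfig
from oralpv.vocab import AETermFrame, load_default_frame


@pytest.fixture(scope="session")
def default_frame() -> AETermFrame:
    return load_default_frame()


@pytest.fixture()
def small_frame() -> AETermFrame:
    return AETermFrame(
        entries={
            "ageusia": "taste",
            "oral herpes": "oral_mucosa",
            "lip swelling": "lips",
            "dry mouth": "salivary_glands",
        },
        exclusion_keywords=("contracept", "cancer"),
    )


def record(
    rid: str,
    terms,
    sex: str = "female",
    age: str = "18to59",
    vtype: str = "mrna",
    schedule: str = "primer",
    year: int = 2021,
    vclass: str = "covid19",
) -> ICSRRecord:
    if isinstance(terms, str):
        terms = (terms,)
    return ICSRRecord(
        report_id=rid,
        sex=sex,
        age_group=age,
        vaccine_type=vtype,
        schedule=schedule,
        year=year,
        vaccine_class=vclass,
        terms=tuple(terms),
    )


def single_collection(records) -> ICSRCollection:
    return ICSRCollection.from_records(list(records), "single_term")


def multi_collection(records) -> ICSRCollection:
    return ICSRCollection.from_records(list(records), "multi_term")


def simple_marginals(
    female: float = 0.5,
    minors: float = 0.0,
    seniors: float = 0.2,
    vector: float = 0.2,
    booster: float = 0.1,
    missing_sex: float = 0.0,
) -> dict:
    sex = {"female": female * (1 - missing_sex), "male": (1 - female) * (1 - missing_sex)}
    if missing_sex:
        sex["missing"] = missing_sex
    adults = 1.0 - minors - seniors
    return {
        "sex": sex,
        "age_group": {"7to17": minors, "18to59": adults, "over59": seniors},
        "vaccine_type": {"mrna": 1.0 - vector, "viral_vector": vector},
        "schedule": {"primer": 1.0 - booster, "booster": booster},
        "year": {"2021": 0.6, "2022": 0.4},
    }


def simple_sim_config(
    term_rates: dict[str, float],
    n1: int = 2000,
    n2: int = 2000,
    effects: dict | None = None,
    comparator_fraction: float = 0.0,
    comparator_term_rates: dict | None = None,
    seed: int = 0,
    **marginal_kwargs,
) -> SimConfig:
    m = simple_marginals(**marginal_kwargs)
    return SimConfig(
        n_reports_db1=n1,
        n_reports_db2=n2,
        covariate_marginals={"db1": m, "db2": m},
        term_rates=term_rates,
        covariate_effects=effects or {},
        comparator_fraction=comparator_fraction,
        comparator_term_rates=comparator_term_rates or {},
        seed=seed,
    )
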