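import numpy as np
import pytest

import facility_readiness as fr
from facility_readiness.core import (Framework, ManagingAuthority, MatrixPurpose,
                                     Response, Tier)
from facility_readiness.registry import IndexSpec, ItemDefinition, ItemRegistry
from facility_readiness.survey_io import FacilityRecord, ResponseMatrix


@pytest.fixture(scope="session")
def registry():
    return fr.default_registry()


@pytest.fixture(scope="session")
def preset_cohort(registry):
    """One calibrated synthetic cohort (160 hospitals + 246 health centres)."""
    cfg = fr.preset_paper_like(20250901)
    return fr.generate_cohort(cfg, registry)


@pytest.fixture(scope="session")
def cohort_by_tier(preset_cohort):
    return fr.split_by_tier(preset_cohort)


def make_toy_registry(item_ids, domain="d1", framework=Framework.SARA,
                      domains=None, conditional=None):
    """Small registry for I/O and coding tests (no count validation)."""
    items = []
    for i, iid in enumerate(item_ids):
        items.append(ItemDefinition(
            item_id=iid, label=iid,
            domain=domains[i] if domains else domain,
            frameworks=frozenset({framework}),
            conditional_applicability=(conditional or {}).get(iid)))
    return ItemRegistry(items)


def make_spec(item_ids, tier=Tier.HOSPITAL, domains=None,
              framework=Framework.SARA, excluded=frozenset()):
    if domains is None:
        domains = {"d1": tuple(item_ids)}
    return IndexSpec(name=framework, tier=tier, items=tuple(item_ids),
                     domains={d: tuple(v) for d, v in domains.items()},
                     excluded_domains_for_weighting=frozenset(excluded))


def make_record(fid, responses, tier=Tier.HOSPITAL,
                authority=ManagingAuthority.GOVERNMENT, volume=None):
    return FacilityRecord(
        facility_id=fid, tier=tier, managing_authority=authority,
        region="Amhara", responses={k: Response(v) for k, v in responses.items()},
        monthly_delivery_volume=volume)


def make_matrix(values, purpose=MatrixPurpose.ADDITIVE, applicable=None,
                tier=Tier.HOSPITAL, item_ids=None, facility_ids=None):
    values = np.asarray(values)
    n, p = values.shape
    if applicable is None:
        applicable = np.ones((n, p), dtype=bool)
    return ResponseMatrix(
        facility_ids=facility_ids or [f"f{i}" for i in range(n)],
        item_ids=item_ids or [f"i{j}" for j in range(p)],
        values=values, applicable=np.asarray(applicable, dtype=bool),
        purpose=purpose, tier=tier)


def simulate_2pl_matrix(n, a, b, mean=0.0, seed=0):
    """Binary item matrix from the latent-trait logistic model."""
    rng = np.random.default_rng(seed)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    theta = rng.normal(mean, 1.0, size=n)
    prob = 1.0 / (1.0 + np.exp(-a * (theta[:, None] - b)))
    values = (rng.random((n, len(a))) < prob).astype(np.int8)
    return make_matrix(values), theta
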