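#!/usr/bin/env python
"""Per-item diagnostics behind the item-selection procedure: per-tier
availability, the >97% near-universal screen, per-domain 2PL
discrimination/difficulty, interitem correlation and internal
consistency (Cronbach's alpha) per framework. Writes
results/item_diagnostics_<tier>.csv and results/internal_consistency.csv.
"""

from pathlib import Path

import pandas as pd

import facility_readiness as fr
from facility_readiness.core import Framework, MatrixPurpose, Tier
from facility_readiness.errors import ReadinessError
from facility_readiness.survey_io import ResponseMatrix

OUT = Path(__file__).resolve().parents[1] / "results"


def submatrix(mx: ResponseMatrix, items: list[str]) -> ResponseMatrix:
    cols = [mx.item_ids.index(i) for i in items]
    return ResponseMatrix(mx.facility_ids, items, mx.values[:, cols],
                          mx.applicable[:, cols], mx.purpose, mx.tier)


def main() -> None:
    registry = fr.default_registry()
    consistency_rows = []
    for tier, stem in ((Tier.HOSPITAL, "hospitals"),
                       (Tier.HEALTH_CENTRE_CLINIC, "health_centres")):
        records = fr.read_facility_survey(OUT / f"survey_{stem}.csv", registry)
        rows = []
        for fw in Framework:
            spec = fr.load_index_spec(fw, tier, registry)
            mx = fr.code_responses(records, spec, MatrixPurpose.ADDITIVE)
            avail = fr.availability(mx)
            _, excluded = fr.screen_universal(avail)
            try:
                alpha_overall = fr.cronbach_alpha(mx)
                mean_r, _, _, _ = fr.interitem_correlation(mx)
            except ReadinessError:
                alpha_overall = mean_r = float("nan")
            consistency_rows.append({
                "tier": tier.value, "framework": fw.value, "domain": "(all)",
                "alpha": alpha_overall, "mean_interitem_r": mean_r})
            for domain, members in spec.domains.items():
                sub = submatrix(mx, list(members))
                try:
                    fit = fr.fit_2pl(sub)
                except ReadinessError:
                    fit = None
                try:
                    alpha_d = fr.cronbach_alpha(sub)
                except ReadinessError:
                    alpha_d = float("nan")
                consistency_rows.append({
                    "tier": tier.value, "framework": fw.value, "domain": domain,
                    "alpha": alpha_d, "mean_interitem_r": float("nan")})
                for diag in fr.build_item_diagnostics(sub, fit):
                    rows.append({"item_id": diag.item_id, "framework": fw.value,
                                 "domain": domain,
                                 "availability": diag.availability,
                                 "excluded_universal": diag.excluded_universal,
                                 "a": diag.discrimination_a,
                                 "b": diag.difficulty_b,
                                 "converged": diag.fit_converged})
            variation = fr.classify_item_variation(avail)
            print(f"{stem:15s} {fw.value:13s}: {len(excluded)} items >97% "
                  f"available; {variation.pct_widely_available}% of items >=90%, "
                  f"{variation.pct_rare}% rare (<40%)")
        pd.DataFrame(rows).to_csv(OUT / f"item_diagnostics_{stem}.csv", index=False)
    pd.DataFrame(consistency_rows).to_csv(OUT / "internal_consistency.csv",
                                          index=False)
    print("shorter frameworks lean on widely available items; internal "
          "consistency per domain is written to internal_consistency.csv")


if __name__ == "__main__":
    main()
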