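"""Assigned versus closest facility: does reassignment help?

Runs the full pipeline, then compares each fokontany's travel time to its
administratively assigned health center / supply point against the
closest one (the facility minimising the fokontany mean).  Reassignment
can only shorten trips; the interesting question is by how much.
"""

from chw_access import LandscapeSpec, bin_travel_times, generate, run_pipeline

land = generate(LandscapeSpec(seed=7))
res = run_pipeline(land)

for kind in ("CSB", "PA"):
    ok = res.scenarios[(res.scenarios.facility_kind == kind) & (~res.scenarios.excluded)]
    if ok.empty:
        continue
    mis = (ok.assigned_id != ok.closest_id).mean()
    print(f"\n{kind}: {len(ok)} fokontany, {mis:.0%} not assigned to their closest facility")
    for scen, col in (("assigned", "assigned_minutes"), ("closest", "closest_minutes")):
        b = bin_travel_times(ok[col])
        print(f"  {scen:>8}: mean {ok[col].mean()/60:.2f} h | "
              f"<=2h {b['le_2h']:.0%}, 2-4h {b['2_to_4h']:.0%}, >4h {b['gt_4h']:.0%}")

excl = res.scenarios[res.scenarios.excluded]
if len(excl):
    print(f"\nexcluded: {excl.exclusion_reason.value_counts().to_dict()}")
print("\n" + res.report)
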