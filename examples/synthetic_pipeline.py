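"""Full pipeline on a synthetic specimen with known ground truth.

A century-long pH history (quasi-decadal 7.7-7.9 oscillation plus a +0.2
ramp over 1980-2000) is forward-modelled into band d11B / B/Ca records and
a Mg/Ca transect; the pipeline then re-dates the bands, screens worm-
contaminated ones, and reconstructs pH with Monte-Carlo uncertainties.
"""

from boronph.chronology import assign_years, count_cycles
from boronph.proxy import reconstruct
from boronph.screening import screen
from boronph.synthetic import ScenarioSpec, generate

spec = ScenarioSpec(seed=42)
data = generate(spec)

model = count_cycles(data["transect"], spec.collection)
dated = assign_years(data["bands"].drop(columns=["year_ce"]), model)
ok = (dated["year_ce"].to_numpy() == data["bands"]["year_ce"].to_numpy()).mean()
print(f"chronology : {model.n_years} annual increments, {ok:.0%} of bands dated correctly")

flagged = screen(data["bands"], with_fraction=False)
truth = data["truth"]
n_true = int(truth["contaminated"].sum())
n_flag = int((flagged["flag"] != "ok").sum())
print(f"screening  : {n_flag} bands flagged ({n_true} truly contaminated)")

rec = reconstruct(flagged, data["env"], n_draws=2000, seed=1)
merged = rec.merge(truth[["year_ce", "pH_true"]], on="year_ce")
pre = merged[merged.year_ce < spec.step_start]
post = merged[merged.year_ce >= spec.step_end]
step = post.pH_median.mean() - pre.pH_median.mean()
true_step = post.pH_true.mean() - pre.pH_true.mean()
cov = ((merged.pH_true >= merged.ci68_lo) & (merged.pH_true <= merged.ci68_hi)).mean()
print(f"recovery   : pH step {step:+.3f} (truth {true_step:+.3f}); "
      f"68% envelope covers truth for {cov:.0%} of years")
print()
print("The +0.2 step injected after 1980 is recovered from the noisy,")
print("screened records; envelope coverage exceeds 68% here because the")
print("conservative T/S/calibration uncertainties are systematic in a")
print("single-specimen scenario.")
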