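"""Simulate one dataset and fit it with all three estimators.

Shows the practical difference between the estimators: scale regression (SR)
attenuates the interaction coefficients because products of noisy scale means
are noisier than the scales themselves, while factor score regression (FSR)
and the unconstrained product indicator approach (UPI) model the measurement
error and stay close to the population values.
"""

from nlsempower import (
    fit_fsr,
    fit_sr,
    fit_upi,
    moderated_mediation_model,
    simulate_dataset,
)

spec = moderated_mediation_model("high")
sample = simulate_dataset(spec, n=5000, seed=7)
print(f"simulated {sample.n} observations x {len(sample.columns)} indicators")

keys = ["Eta2~Eta1:Xi1", "Eta2~Xi1:Xi2", "Eta1~Xi1", "Eta1~Xi2"]
truth = {"Eta2~Eta1:Xi1": 0.1, "Eta2~Xi1:Xi2": 0.1, "Eta1~Xi1": 0.2, "Eta1~Xi2": 0.5}

print(f"{'parameter':>14} {'truth':>6} {'SR':>8} {'FSR':>8} {'UPI':>8}")
fits = {
    "SR": fit_sr(sample, spec),
    "FSR": fit_fsr(sample, spec),
    "UPI": fit_upi(sample, spec),
}
for key in keys:
    row = [f"{fits[m].estimates[key]:8.4f}" for m in ("SR", "FSR", "UPI")]
    print(f"{key:>14} {truth[key]:6.2f} " + " ".join(row))
# Expect SR's interaction rows noticeably below .1 (attenuation); FSR and UPI
# scatter around .1 within sampling error (SEs here are roughly .02).
for m, f in fits.items():
    print(f"{m}: converged={f.converged}, SE(Eta2~Eta1:Xi1)="
          f"{f.standard_errors['Eta2~Eta1:Xi1']:.4f}")
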