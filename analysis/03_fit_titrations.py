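"""Simulate and fit two-salt titrations for the reference REs.

Each reference RE's measured Kd values (200 and 275 mM NaCl, WT protein)
seed the generator; noisy curves are refit and the salt-sensitivity index
(Kd_high/Kd_low) is computed.  Large indices flag the electrostatic binding
mode, near-1 indices the hydrophobic mode.  Writes results/titration_fits.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from p53recode import classify, fit_kd, reference_re, salt_sensitivity_index, simulate_titration
from p53recode.reference import KD_NM, reference_res

OUT = Path(__file__).resolve().parent.parent / "results"
NOISE_SD = 5.0  # mP
SEED = 318


def main():
    rng = np.random.SeedSequence(SEED).generate_state(200) % (2**31)
    rows = []
    k = 0
    for re in reference_res():
        kd_low_nM, kd_high_nM, _, _ = KD_NM[re.name]
        fits = {}
        for salt, kd_nM in (("200", kd_low_nM), ("275", kd_high_nM)):
            if kd_nM is None:
                fits[salt] = None
                continue
            curve = simulate_titration(kd_nM * 1e-9, noise_sd=NOISE_SD,
                                       seed=int(rng[k]), salt_mM=float(salt))
            k += 1
            fits[salt] = fit_kd(curve)
        idx = salt_sensitivity_index(
            fits["200"].Kd if fits["200"] else None,
            fits["275"].Kd if fits["275"] else None,
        )
        rows.append({
            "name": re.name,
            "kd_true_200mM_nM": kd_low_nM,
            "kd_fit_200mM_nM": round(fits["200"].Kd * 1e9, 1) if fits["200"] else None,
            "kd_true_275mM_nM": kd_high_nM,
            "kd_fit_275mM_nM": round(fits["275"].Kd * 1e9, 1) if fits["275"] else None,
            "salt_sensitivity_index": round(idx, 2) if np.isfinite(idx) else None,
            "predicted_mode": classify(re).mode_label,
        })
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "titration_fits.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    print("\nNote: electrostatic-mode REs show the largest salt-sensitivity "
          "indices; hydrophobic-mode REs sit near 1-4.")
    print(f"Wrote {OUT / 'titration_fits.tsv'}")


if __name__ == "__main__":
    main()
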