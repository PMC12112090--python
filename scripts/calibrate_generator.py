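"""One-off closed-form calibration of the synthetic generator's scale constants.

The generator works on the standardized future-tense scale, so its residual
scales and back-transform are pinned down by the studies' descriptive
marginals rather than free dials:

* sigma1 — the pooled variance of the latent standardized propensity must be
  1, so sigma1^2 = 1 − between-language variance implied by (lambda1, alpha)
  at the cohort's group sizes;
* sigma2 — the within-language log-k variance equals slope^2 * sigma1^2 +
  sigma2^2; sigma2 is solved per language against the descriptive log-k SDs
  and averaged on the variance scale;
* (fut_mean, fut_sd) — the affine back-transform mapping the two languages'
  standardized means onto their descriptive proportion means.

Run: python scripts/calibrate_generator.py
The printed constants are stored in ftrdisc.synth.
"""

import math

# (n_eng, n_dut, lambda1, alpha, beta1, beta2,
#  sd_logk_eng, sd_logk_dut, mean_fut_eng, mean_fut_dut)
STUDIES = {
    "study1": (113, 122, -0.65, 1.36, 0.26, -0.90, 2.11, 1.92, 0.59, 0.33),
    "study2": (301, 305, -0.75, 1.51, -0.07, -0.26, 1.32, 1.38, 0.59, 0.20),
}


def calibrate(n_e, n_d, lam1, alpha, b1, b2, sd_e, sd_d, mfut_e, mfut_d):
    w_e = n_e / (n_e + n_d)
    mu_e, mu_d = lam1 + alpha, lam1
    pooled_mean = w_e * mu_e + (1 - w_e) * mu_d
    between = w_e * (mu_e - pooled_mean) ** 2 + (1 - w_e) * (mu_d - pooled_mean) ** 2
    sigma1 = math.sqrt(1.0 - between)
    var_e = sd_e ** 2 - (b1 + b2) ** 2 * sigma1 ** 2
    var_d = sd_d ** 2 - b1 ** 2 * sigma1 ** 2
    sigma2 = math.sqrt((var_e + var_d) / 2.0)
    fut_sd = (mfut_e - mfut_d) / alpha
    fut_mean = mfut_d - lam1 * fut_sd
    return sigma1, sigma2, fut_mean, fut_sd


def main():
    for study, args in STUDIES.items():
        sigma1, sigma2, fut_mean, fut_sd = calibrate(*args)
        print(f"{study}: sigma1={sigma1:.4f} sigma2={sigma2:.4f} "
              f"fut_mean={fut_mean:.4f} fut_sd={fut_sd:.4f}")


if __name__ == "__main__":
    main()
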