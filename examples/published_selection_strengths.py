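"""Relative selection strength from published oryx coefficients.

Loads the final-model (M4) coefficient table reported for the reintroduced
scimitar-horned oryx population in Chad and shows the RSS = exp(coefficient)
identity, then evaluates an RSS curve for dry-season aNDVI with its quadratic
term: selection for greener-than-usual vegetation that saturates and turns
over at high anomalies (a hump-shaped response).
"""
import numpy as np
import pandas as pd

from stepsel import model as mod
from stepsel import published, rss

table = published.published_coefficients()
dry = table[(table["period"] == "dry") & table["consistent"]]
check = np.abs(np.exp(dry["coefficient"]) - dry["rss"]).max()
print(f"dry-period table: {len(dry)} rows; max |exp(coef) - printed RSS| = {check:.2e}")

show = dry[dry["term"].isin(["aNDVI", "dNDVI", "elevation", "TRI", "temperature"])]
print("\nenvironmental main effects (dry period):")
print(show[["term", "coefficient", "rss", "significant"]]
      .to_string(index=False, float_format=lambda v: f"{v:.4f}"))

# rebuild a FitResult carrying the published point estimates (diagonal
# covariance from the printed SEs) to drive the curve machinery
terms = dry.set_index("term")
names = ["aNDVI", "aNDVI^2"]
fit = mod.FitResult(
    beta=pd.Series({t: terms.loc[t, "coefficient"] for t in names}),
    cov_naive=np.diag([terms.loc[t, "se"] ** 2 for t in names]),
    cov_robust=np.diag([terms.loc[t, "se"] ** 2 for t in names]),
    loglik=0.0, loglik_null=0.0, k=2, n_strata=10 ** 5, n_clusters=32,
    converged=True, n_iter=0, period="dry", tier="M4")

curve = rss.log_rss_curve(fit, "aNDVI", grid=np.linspace(-2, 3, 11))
print("\nRSS curve for aNDVI (reference = period mean, standardized scale):")
print(curve[["x", "rss", "lo", "hi"]]
      .to_string(index=False, float_format=lambda v: f"{v:.3f}"))
b1 = terms.loc["aNDVI", "coefficient"]
b2 = terms.loc["aNDVI^2", "coefficient"]
print(f"\nselection rises across the observed range; the negative quadratic "
      f"({b2:+.4f}) makes the response concave, with the turnover at "
      f"{-b1 / (2 * b2):+.1f} SD — a hump-shaped preference for "
      "greener-than-usual sites")
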