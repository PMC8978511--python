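"""Compare all five models on one synthetic study with CPC and IG.

CPC (Common Part of Commuters, in [0, 1], higher is better) is the
Sorensen-Dice overlap of predicted and observed flow vectors; IG
(Information Gain, >= 0, lower is better) is a KL-style error.  The summary
splits the window into P1 (before widespread interventions) and P2.
"""

from mobiflux.pipeline import run_pipeline

config = {
    "synth": {"n_countries": 20, "n_days": 45},
    "models": ["gravity-exp", "gravity-pow", "radiation", "cgm-exp", "cgm-pow"],
    "fit_scope": "per-day",
}
result = run_pipeline(config, "scratch/example_out", seed=8)
cols = ["model", "direction", "mu_cpc", "mu_cpc_p1", "mu_cpc_p2", "mu_ig"]
print(result["summary"][cols].round(3).to_string(index=False))
print("\nFlows here are generated by a stringency-driven (CGM, power-kind) "
      "world, so the power-kind models fit best; mu_cpc_p2 < mu_cpc_p1 for "
      "stringency-blind models reflects the restriction-driven decline.")
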