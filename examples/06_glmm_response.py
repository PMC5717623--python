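"""Random-intercept GLMM: do homogeneous gestures elicit emotional responses?

Each responded-to gesture is one observation; the focal signaller enters as
a random intercept because its gestures are not independent of each other.
The generator plants P(emotional | homogeneous) = 0.60 and
P(goal-directed | heterogeneous) = 0.75, so the fixed effect of gesture
homogeneity on an emotional response should be positive.
"""

import pandas as pd

from gestnet import GlmmSpec, SyntheticConfig, fit_glmm, generate_dataset

config = SyntheticConfig(seed=42)
individuals, _, repertoires, _, events = generate_dataset(config)

rows = []
for e in events:
    if not e.response_present:
        continue
    recipient = repertoires.get(e.recipient_id)
    if recipient is None:
        continue
    rows.append(
        {
            "emotional": 1.0 if e.response_type == "emotional" else 0.0,
            "homogeneous": 1.0 if e.gesture_type in recipient.present else 0.0,
            "focal": e.signaller_id,
        }
    )
data = pd.DataFrame(rows)
print(f"{len(data)} responded-to gestures, "
      f"{data.homogeneous.mean():.0%} homogeneous")

spec = GlmmSpec("emotional", "binomial_logit", ("homogeneous",), "focal")
fit = fit_glmm(data, spec)
for term in ("intercept", "homogeneous"):
    print(f"  {term:12s} beta = {fit.estimate(term):+.3f} "
          f"(s.e. {fit.se(term):.3f}, p = {fit.estimates.loc[term, 'p']:.4f})")
print(f"  random-intercept variance = {fit.random_intercept_var:.3f}, "
      f"converged = {fit.converged}")
# A positive homogeneity coefficient on the logit scale means shared
# gesture types shift responses toward emotional displays, as planted.
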