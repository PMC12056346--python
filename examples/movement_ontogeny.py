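"""Movement demo: ontogeny and consistency of migratory strategy.

Simulates a GPS-tracked cohort (juveniles followed from fledging, adults
tagged as breeders), classifies every bird-winter from its wintering
latitude, and quantifies the two signatures of developmental plasticity:
migration probability falling with age, and adults being far more
repeatable in their wintering choice than immature birds.
"""

import numpy as np
import pandas as pd

from ciconia import movement, synthgen

params = synthgen.TrackSimParams()
juveniles = synthgen.sim_tracks(params, 200, 5, seed=1, start_age=1)
adults = synthgen.sim_tracks(params, 100, 5, seed=2, start_age=4)
adults["bird_id"] = "ad_" + adults["bird_id"]
birds = pd.concat([juveniles, adults], ignore_index=True)

# classify from latitude (matches the generator's labels by construction)
birds["strategy"] = movement.classify_strategy(birds["winter_lat"]).to_numpy()

print("migrant fraction by age class")
for age, sub in birds.groupby(np.minimum(birds["age"], 4)):
    label = "adult" if age == 4 else f"age {age}"
    print(f"  {label:6s}: {(sub['strategy'] == 'migrant').mean():.2f}")

model = movement.fit_age_model(birds)
print(f"\nage GLMM slope (logit/yr): {model.slope:.2f} +- {model.slope_se:.2f}"
      f"  (random-intercept SD {model.re_sd:.2f}, n = {model.n})")

ad = birds[birds["age"] >= 4]
juv = birds[birds["age"] < 4]
r_ad = movement.repeatability(ad["winter_lat"], ad["bird_id"], n_boot=200, seed=3)
r_juv = movement.repeatability(juv["winter_lat"], juv["bird_id"], n_boot=200, seed=4)
print(f"adult repeatability    : R = {r_ad.R:.3f} (SE {r_ad.se:.3f}, p = {r_ad.p_value:.2g})")
print(f"juvenile repeatability : R = {r_juv.R:.3f} (SE {r_juv.se:.3f}, p = {r_juv.p_value:.2g})")

trans = movement.transition_summary(birds)
print(f"adult strategy switches: {trans['switches']} of {trans['transitions']} transitions")
print(
    "\nThe negative slope is the ontogenetic loss of migration; the adult/juvenile\n"
    "repeatability gap says the strategy is plastic while young and fixed as adult."
)
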