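"""Generate a synthetic screening registry and inspect its structure.

Builds a small seeded population of screen-eligible adults (age 50-74)
nested within primary-care physicians, with colonoscopy events over a
5-year window and colorectal-cancer outcomes over 12 years.
"""

import screenbias as sb

cfg = sb.default_config(seed=7, n_pcps=300)  # ~30,000 subjects
registry = sb.generate_registry(cfg)
subj = registry.subjects

print(f"physicians: {len(registry.pcps)}, subjects: {len(subj)}")
print(f"female share:            {(subj['sex'] == 'F').mean():.3f}")
print(f"screening colonoscopy:   {subj['screening_year'].notna().mean():.3f}")
print(f"diagnostic colonoscopy:  {subj['diagnostic_year'].notna().mean():.4f}")
print(f"any CRC diagnosis:       {subj['crc_dx_year'].notna().mean():.4f}")
print(f"CRC death:               {subj['crc_death_year'].notna().mean():.4f}")

arr = sb.true_marginal_arr(cfg, subj, "incidence")
print(f"true causal ARR of screening on incidence: {arr:.3f} pp")
print("(negative = protective; every estimator downstream is judged "
      "against this counterfactual quantity)")
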