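"""The cohort-construction paradox: one registry, two opposite answers.

In the unselected cohort, exposure and outcomes are measured over the
same years, so the diagnostic colonoscopy triggered by an incipient
cancer counts as exposure and screening appears to *cause* cancer.
Restricting to subjects alive and cancer-free after the exposure
window (and to physicians with a real screening practice) flips the
sign.
"""

import screenbias as sb

registry = sb.generate_registry(sb.default_config(seed=1))

for kind, build in (("unselected", sb.build_unselected_cohort),
                    ("restricted", sb.build_restricted_cohort)):
    cohort = build(registry)
    est = sb.unadjusted_risk_difference(cohort.rows, "crc_incident")
    print(f"{kind:>10} cohort (n={cohort.counts['n_subjects']:,}): "
          f"incidence {est.p_exposed:.2f}% (scoped) vs {est.p_unexposed:.2f}% "
          f"(not scoped); difference {est.arr:+.2f} pp")

print("\nA positive difference in the unselected cohort is pure "
      "measurement error, not biology: the cancer caused the colonoscopy.")
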