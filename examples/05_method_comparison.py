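"""One-command pipeline: simulate, build both cohorts, run every method.

Produces the full method-comparison table (per cohort and outcome) and
writes all artifacts -- registry export, cohort CSVs with flow counts,
balance and Kaplan-Meier tables, manifest -- to ./comparison_run/.
"""

import screenbias as sb

table = sb.run_pipeline(sb.default_config(seed=1, n_pcps=500),
                        outdir="comparison_run")
print(table.to_text())
print("Reading the table: negative ARR = protective. The unselected "
      "cohort's positive ARR is the measurement-error artifact; in the "
      "restricted cohort all methods agree on a protective effect, with "
      "the IV interval widest.")
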