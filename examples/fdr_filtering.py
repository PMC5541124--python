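"""Target-decoy q-values and the two-stage identification filter.

Builds a tiny PSM set with two decoys, prints the q-value of every PSM next
to the exhaustive-threshold FDR it derives from, and applies the study's
filter (1% peptide FDR and Mascot score floor 18).
"""

from isoreg import FilterConfig, PSMRecord, apply_filter, estimate_qvalues


def psm(psm_id, score, decoy=False):
    return PSMRecord(psm_id=psm_id, experiment_id="exp1", peptide="PEPTIDEK",
                     accession="DECOY_X" if decoy else "TARGET", score=score,
                     is_decoy=decoy, intensities={114: 1.0, 115: 1.0, 116: 1.0})


psms = [psm("t1", 42.0), psm("t2", 35.0), psm("t3", 24.0), psm("t4", 17.5),
        psm("d1", 26.0, decoy=True), psm("d2", 12.0, decoy=True)]

annotated = estimate_qvalues(psms)
for p in sorted(annotated, key=lambda p: -p.score):
    kind = "decoy " if p.is_decoy else "target"
    print(f"{p.psm_id}  {kind}  score {p.score:5.1f}  q = {p.q_value:.3f}")

kept = apply_filter(annotated, FilterConfig(fdr_threshold=0.01, score_floor=18.0))
print()
print("retained at 1% FDR + score >= 18:", [p.psm_id for p in kept])
print("t3 and t4 score at or below the best decoy, so their q-values (decoys")
print("over targets at or above their score) exceed the 1% threshold; t4 also")
print("fails the score floor of 18; decoys never pass the filter.")
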