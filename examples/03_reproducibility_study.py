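"""Two-session test-retest study: paired t-test and ICC per region.

Sixteen simulated subjects are each scanned twice; between-subject
perfusion differences are real, within-subject differences are acquisition
noise.  The cortex (large ΔM, many voxels) is a high-SNR measurement and
reproduces almost perfectly; the medulla (about four-fold smaller
difference signal) agrees less well — the same contrast seen between
cortical and medullary test-retest agreement in renal ASL studies.
"""
from aslkid import ReproStudyConfig, run_repro_study

report = run_repro_study(ReproStudyConfig(n_subjects=16, seed=0))
print(f"{'region/PLD':18s} {'ICC':>7s} {'paired-t p':>11s}")
for key, entry in report["results"].items():
    p = entry["paired_t"].get("p")
    p_txt = f"{p:.3f}" if p is not None else "n/a"
    print(f"{key:18s} {entry['icc']:7.3f} {p_txt:>11s}")
# ICC near 1 = between-subject variance dominates measurement error.
# Non-significant paired-t p-values mean no systematic session bias.
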