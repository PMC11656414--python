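"""Segment-wise alignment rescues detection under chemical-shift jitter.

Ionizable compounds drift in chemical shift from fraction to fraction.
This script runs the same 59-compound / 69-fraction study twice — once
correlating the raw jittered spectra, once after pairwise-sequential
segment alignment — and compares how many true actives each run recovers.
"""

import warnings

import hetcakit as hk

warnings.simplefilter("ignore", UserWarning)


def run(align: bool):
    design = hk.preset("misalignment", seed=0)
    spectra, activity, truth = hk.simulate(design)
    masked = hk.apply_exclusions(spectra)
    if align:
        masked = hk.align_set(masked).aligned
    buckets = hk.bucket(masked, 0.01)
    ps = hk.hetca(buckets, activity)
    lib = hk.library_from_design(design, truth)
    return hk.score_detection(hk.detect_compounds(ps, lib), lib.true_labels)


for align in (False, True):
    rep = run(align)
    label = "aligned  " if align else "unaligned"
    print(f"{label}: sensitivity {rep.sensitivity():.2f} "
          f"({rep.n_correct_active}/{rep.n_true_active} actives), "
          f"FP={rep.false_positives}")

print("\nwith 0.01 ppm per-fraction jitter the raw spectra scramble the")
print("bucket/activity correlation; aligning each spectrum to its")
print("already-aligned predecessor restores a large part of the signal.")
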