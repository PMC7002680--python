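"""Fold-improvement of separation accuracy over the TrueColor baseline.

Runs the two spectral-overlap regimes (maxima 0-8.9 nm apart and
17.8-35.6 nm apart) over ten noise seeds and prints the mean ratio of
separation accuracies: phasor rendering / Gaussian-kernel TrueColor.
"""

from seerpy.workflows import separation_benchmark

rows = separation_benchmark(seeds=range(1, 11))
print(f"{'d1 (nm)':>8s} {'d2 (nm)':>8s} {'sep SEER':>9s} {'sep TC':>8s} {'ratio':>7s}")
for r in rows:
    print(f"{r['d1']:8.1f} {r['d2']:8.1f} {r['sep_seer']:9.3f} "
          f"{r['sep_truecolor']:8.3f} {r['ratio']:7.2f}")
print("\nratio > 1: the phasor rendering separates the three chart regions")
print("into more distinct colors than the TrueColor compression.")
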