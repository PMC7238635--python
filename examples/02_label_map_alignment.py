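"""Align an in-silico digest to a noisy optical map.

Digests a random 500-kb sequence at the CTTAAG motif, simulates an
optical-map copy with sqrt-length sizing noise and missed labels, aligns
the two label maps, and prints the pairing.  The confidence is the
alignment score in decibans: a few hundred for a full-length match,
near the reporting floor for chance pairings.
"""
import numpy as np

from mapweaver.core import LabelMap, SequenceRecord
from mapweaver.optical import AlignParams, align_label_maps, fit_stretch, insilico_digest

rng = np.random.default_rng(0)
seq = np.frombuffer(b"ACGT", dtype=np.uint8)[
    rng.integers(0, 4, 500_000)].tobytes().decode()
digest = insilico_digest(SequenceRecord("contig", seq))
print(f"digest: {digest.n_labels} labels over {digest.length_bp / 1e3:.0f} kb")

# a noisy "optical" copy: per-interval Gaussian sizing error, 5% missed labels
labels = np.asarray(digest.labels)
intervals = np.diff(np.concatenate([[0.0], labels]))
noisy = np.cumsum(intervals + rng.normal(0, 3.0 * np.sqrt(intervals)))
keep = rng.random(noisy.size) >= 0.05
optical = LabelMap("map", float(noisy[-1] + 500), noisy[keep].tolist(),
                   source="optical")

aln = align_label_maps(digest, optical, AlignParams())[0]
print(f"alignment: {aln.n_pairs} label pairs, orientation {aln.orientation}, "
      f"confidence {aln.confidence:.1f}")
stretch = fit_stretch(aln, digest, optical)
print(f"rescaling factor (query onto map): {stretch:.5f} "
      "(1.0 = no systematic stretch)")
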