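"""Estimating repertoire size: how many syllable types does a bird sing?

Fits Gaussian mixtures with increasing component counts to the song's
distribution in similarity-space and picks the count minimizing a
three-fold cross-validated BIC.  For a song built from 5 distinct types,
the chosen K should land on (or next to) 5.
"""

import songdkl as sk

spec = sk.SongSpec(repertoire=sk.default_repertoire(5, seed=4),
                   n_renditions=150, seed=4)
wav, truth = sk.render_song(spec)

psds = [sk.syllable_psd(s)
        for s in sk.segment_recording(sk.highpass(wav))]
basis = sk.build_basis(psds, n_basis=20, seed=0)
sim = sk.similarity_matrix(psds, basis)

model, report = sk.select_model(sim.values, k_grid=tuple(range(2, 11)),
                                seed=0)
print("candidate K :", report.k_grid)
print("cv-BIC      :", [f"{s:.0f}" for s in report.cv_bic])
print(f"estimated number of syllable types: {report.chosen_k} "
      f"(true: {truth['type'].nunique()})")
# The cv-BIC dips at the true type count and rises as extra components
# start fitting rendition noise.
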