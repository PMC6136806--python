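"""Song D_KL: how much of a tutor's song is missing from a tutee's?

Compares one tutor song against three comparison songs: a faithful copy
(same repertoire, new renditions), a copy missing one syllable type, and
an unrelated song.  Song D_KL is the estimated KL divergence, in bits,
between mixture models of the two repertoires in the tutor's
similarity-space: near zero for good copies, large when tutor content is
absent from the comparison.
"""

import songdkl as sk

tutor_spec = sk.SongSpec(repertoire=sk.default_repertoire(6, seed=10),
                         n_renditions=200, seed=10)
tutor = [sk.syllable_psd(s) for s in
         sk.segment_recording(sk.highpass(sk.render_song(tutor_spec)[0]))]

comparisons = {
    "faithful copy": sk.render_tutee(
        sk.TuteeSpec(base=tutor_spec, seed=31))[0],
    "missing one type": sk.render_tutee(
        sk.TuteeSpec(base=tutor_spec, omit_types=(2,), seed=32))[0],
    "unrelated song": sk.render_song(
        sk.SongSpec(repertoire=sk.default_repertoire(6, seed=20),
                    n_renditions=200, seed=20))[0],
}

basis = sk.build_basis(tutor, n_basis=15, seed=0)
cfg = sk.DklConfig(k_grid=tuple(range(2, 9)), seed=0)
for name, wav in comparisons.items():
    comp = [sk.syllable_psd(s)
            for s in sk.segment_recording(sk.highpass(wav))]
    s_ref, s_comp = sk.project_pair(tutor, comp, basis)
    res, _, _ = sk.song_dkl(s_ref.values, s_comp.values, cfg)
    print(f"{name:18s} Song D_KL = {res.dkl_bits:8.2f} bits "
          f"(SE {res.se_bits:.2f})")
# Expected ordering: faithful copy << missing one type << unrelated song.
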