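"""Innovation: comparison-song content absent from the reference.

Song D_KL is asymmetric.  A tutee that sings everything the tutor sings
plus one novel type scores low when the tutor is the reference (nothing
missing), but reversing the roles — tutee as reference — exposes the
novel type as content the tutor's model cannot encode.
"""

import songdkl as sk

tutor_spec = sk.SongSpec(repertoire=sk.default_repertoire(6, seed=10),
                         n_renditions=200, seed=10)
novel = sk.SyllableSpec(kind="harmonic_stack", f0_hz=5200.0,
                        duration_ms=90.0)
tutee_spec = sk.TuteeSpec(base=tutor_spec, innovate=(novel,), seed=33)

tutor = [sk.syllable_psd(s) for s in
         sk.segment_recording(sk.highpass(sk.render_song(tutor_spec)[0]))]
tutee = [sk.syllable_psd(s) for s in
         sk.segment_recording(sk.highpass(sk.render_tutee(tutee_spec)[0]))]

cfg = sk.DklConfig(k_grid=tuple(range(2, 9)), seed=0)

basis = sk.build_basis(tutor, n_basis=15, seed=0)
s_ref, s_comp = sk.project_pair(tutor, tutee, basis)
learning, _, _ = sk.song_dkl(s_ref.values, s_comp.values, cfg)

basis_t = sk.build_basis(tutee, n_basis=15, seed=0)
s_ref, s_comp = sk.project_pair(tutee, tutor, basis_t)
innovation, _, _ = sk.innovation_dkl(s_ref.values, s_comp.values, cfg)

print(f"tutor as reference (learning):  {learning.dkl_bits:8.2f} bits")
print(f"tutee as reference (innovation): {innovation.dkl_bits:8.2f} bits")
# The first number stays near zero (the tutee copied everything); the
# second is elevated (the tutor never sings the novel type).
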