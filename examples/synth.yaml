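# EHoS-like profile: 8 sets, 700 memories, Table-style uniqueness mix
n_sets: 8
i_tot: 700
target_m: [328, 190, 29, 22, 24, 117, 9, 59]
set_names: [first_name, last_name_title, century, state, position, dynasty_party, cause_of_death, reign]
planted_features: []
seed: 1
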