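sample	ammonia_mgN_l	nitrite_mgN_l	nitrate_mgN_l
Filtrate	716.0	69.6	20.8
PN-effluent	462.0	424.8	46.2
Anammox-effluent	56.0	28.0	48.2
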