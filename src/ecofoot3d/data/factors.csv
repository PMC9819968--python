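land_type,equivalence_factor,yield_factor
croplands,3.39,1.74
forests,1.1,0.86
grazing_lands,0.56,0.51
fishing_grounds,0.44,0.74
carbon_capture_land,1.1,0
built_up,3.39,1.74
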