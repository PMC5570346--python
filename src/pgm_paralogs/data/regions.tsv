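label	col_start	col_stop
phosphoserine	172	182
metal_binding	361	367
sugar_binding	462	473
po4_binding	599	613
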