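151baaa6927d44480b703c87cb25520f2cd767d262d4baaa292fbdfd63d12207
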