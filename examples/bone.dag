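unloading [exposure]
strength [outcome]
unloading -> formation [sign=-]
unloading -> resorption [sign=+]
formation -> mass [sign=+]
formation -> trabecular [sign=+]
resorption -> mass [sign=-]
resorption -> trabecular [sign=-]
mass -> strength [sign=+]
trabecular -> strength [sign=+]
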