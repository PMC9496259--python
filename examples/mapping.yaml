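# Map DAG nodes to dataset columns. An entry may be a single column name or a
# composite: {columns: [...], anchor: <column>} scored by first-PC projection.
nodes:
  unloading: unloading
  formation: formation
  resorption: resorption
  mass: mass
  trabecular: trabecular
  strength: strength
threshold: 0.15
level: 0.95
replicates: 2000
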