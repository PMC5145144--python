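# Single chemosensory bait: the dauer pheromone receptor srg-36.
# Replace with the matching sequence-name ID of your expression table if it
# does not use public gene names.
srg-36
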