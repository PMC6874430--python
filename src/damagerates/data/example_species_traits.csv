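species,max_lifespan_years,avg_lifespan_years,body_weight,heart_rate_bpm
bottlenose dolphin,51.6,25.0,250.0,84.0
goat,20.8,12.0,60.0,85.0
reindeer,21.8,12.0,120.0,60.0
american flamingo,44.0,30.0,2.5,140.0
griffon vulture,41.4,25.0,9.0,110.0
loggerhead sea turtle,76.0,47.0,135.0,25.0
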