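# SimulationConfig overrides for `pssnet simulate`.
n_prescribers: 300
n_clients: 1200
sharing_rate: 2.0
n_innovator_seed: 10
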