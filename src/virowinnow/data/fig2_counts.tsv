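key	count
non_host_total	876528
non_phage_virus	292499
known_SINV-4	126086
known_SINV-1	84769
known_SINV-2	19338
known_SINV-3	353
known_SiDNV	9
assembled_singletons_nonplant_virus	55677
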