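radiation_class,protocol_type,dose_Gy,dose_rate_Gy_per_h,split_interval_h,rejoin_time_h,dsb_per_cell,source_tag
sparsely_ionizing,single,2400.0,7800.0,,72.0,30.2,reported mean (range 24.7-35.6)
sparsely_ionizing,single,1650.0,33.0,,22.0,5.6,reported mean (range 4.2-6.4)
densely_ionizing,single,600.0,1400.0,,72.0,20.1,reported mean (range 9.6-30.9)
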