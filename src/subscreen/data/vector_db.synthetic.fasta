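>vector_arm_left synthetic stand-in for a T/A-cloning vector arm (generated, not a vendor sequence)
GATATCTCATTTCGCACTGCTCCATCACTGCTAATTGGATGAATTACCAATTAATACCAA
CACACATCCAGTTCGTCCTCGGATGTATTTAGGTTATGGGCAATCACCCACTCACCAGAC
>vector_arm_right synthetic stand-in for a T/A-cloning vector arm (generated, not a vendor sequence)
GTTACTTTCTCCATCCAAAGGGGAAACGCTAATTAAACCCCTAGATCAGCGAATCTGCAT
GTTGTGAGGCTTGCAAAGTTCACGCCCACAGCTCAGCCACAAACGATGTCTGATAGGGTC
>ssh_adaptor_1 nested-PCR SSH adaptor 1
CTAATACGACTCACTATAGGGCTCGAGCGGCCGCCCGGGCAGGT
>ssh_adaptor_2r nested-PCR SSH adaptor 2R
CTAATACGACTCACTATAGGGCAGCGTGGTCGCGGCCGAGGT
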