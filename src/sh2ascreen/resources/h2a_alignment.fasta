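>H2A_canonical
SGRGKQGGKARAKAKTRSSRAGLQFPVGRVHRLLRKGNYAERVGAGAPVYLAAVLEYLTAEILELAGNAARDNKKTRIIPRHLQLAIRNDEELNKLLGKVTIAQGGVLPNIQAVLLPKKTESHHKAKGK
>H2A.B_like
SGRGKQGGKARAKAKSRSSRAGLQFPVGQVHRLLRKGNYTERVGAGAPVYLAAVLEYLTAEILELAGNAASDNKKTRIIPRHLQLAIRNDEELNKLLGRVTIAQGGVLPNIQAV---------------
>TH2A_like
SGRGKQGGKARAKAKTRSSRAGLQFPVGRVHRLLRKGNYAERVGAGAPVYLAAVLEYLTAEILELAGNAARDNKKTRIIPRHLQLAIRNDEELNKLLGKVTIAQGGVLPNIQAVLLPKKTESHHKAKGK
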