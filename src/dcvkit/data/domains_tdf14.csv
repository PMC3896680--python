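code,label,definition
D1,Knowledge,An awareness of the existence of something
D2,Skills,An ability or proficiency acquired through practice
D3,Social/professional role and identity,A coherent set of behaviors and displayed personal qualities of an individual in a social or work setting
D4,Beliefs about capabilities,"Acceptance of the truth, reality, or validity about an ability, talent, or facility that a person can put to constructive use"
D5,Optimism,The confidence that things will happen for the best or that desired goals will be attained
D6,Beliefs about consequences,"Acceptance of the truth, reality, or validity about outcomes of a behavior in a given situation"
D7,Reinforcement,"Increasing the probability of a response by arranging a dependent relationship, or contingency, between the response and a given stimulus"
D8,Intentions,A conscious decision to perform a behavior or a resolve to act in a certain way
D9,Goals,Mental representations of outcomes or end states that an individual wants to achieve
D10,"Memory, attention and decision processes","The ability to retain information, focus selectively on aspects of the environment and choose between two or more alternatives"
D11,Environmental context and resources,"Any circumstance of a person's situation or environment that discourages or encourages the development of skills and abilities, independence, social competence, and adaptive behavior"
D12,Social influences,"Those interpersonal processes that can cause individuals to change their thoughts, feelings, or behaviors"
D13,Emotion,"A complex reaction pattern, involving experiential, behavioral, and physiological elements, by which the individual attempts to deal with a personally significant matter or event"
D14,Behavioral regulation,Anything aimed at managing or changing objectively observed or measured actions
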