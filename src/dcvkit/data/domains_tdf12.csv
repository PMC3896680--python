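code,label,definition
D1,Knowledge,Awareness of the existence of something and procedural knowledge about how to act
D2,Skills,An ability or proficiency acquired through practice
D3,Social/professional role and identity,Behaviors and displayed personal qualities of an individual in a social or work setting
D4,Beliefs about capabilities,"Beliefs about one's ability, talent, or facility to perform the behavior, including optimism about succeeding"
D5,Beliefs about consequences,"Beliefs about the outcomes of a behavior in a given situation, including anticipated rewards and punishments"
D6,Motivation and goals,"Intentions, goals, and priorities: the mental representations of outcomes the person wants to achieve and the decision to act"
D7,"Memory, attention and decision processes","The ability to retain information, focus selectively on aspects of the environment and choose between alternatives"
D8,Environmental context and resources,Circumstances of a person's situation or environment that discourage or encourage the behavior
D9,Social influences,"Interpersonal processes that can cause individuals to change their thoughts, feelings, or behaviors"
D10,Emotion,"Affective reaction patterns by which the individual deals with a personally significant matter or event"
D11,Behavioral regulation,Anything aimed at managing or changing objectively observed or measured actions
D12,Nature of the behaviors,"Characteristics of the behavior itself: routines, habits, and the degree to which it is already part of practice"
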